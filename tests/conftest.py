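"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the implementation's code paths:
likelihoods by exhaustive enumeration over internal-state assignments,
transition matrices via scipy's matrix exponential, and incompatibility
scores via exhaustive small-parsimony over all unrooted topologies.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from intron_turnover.mk2_model import MkRates, transition_matrix
from intron_turnover.phylo_io import Phylogeny, PhyleticPattern, TreeNode


# ---------------------------------------------------------------------------
# Random trees (plain numpy, no library tree simulators)
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, n_leaves: int,
                max_branch: float = 1.0) -> Phylogeny:
    """Random binary topology by sequential pair-joining with uniform
    branch lengths."""
    nodes = [TreeNode(f"L{i + 1}", float(rng.uniform(0.01, max_branch)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(None, float(rng.uniform(0.01, max_branch)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    nodes[0].length = 0.0
    return Phylogeny(nodes[0])


def random_pattern(rng: np.random.Generator, tree: Phylogeny,
                   character: str = "trait") -> PhyleticPattern:
    return PhyleticPattern(
        character=character,
        states={lab: int(rng.integers(2)) for lab in tree.leaf_labels()},
    )


# ---------------------------------------------------------------------------
# Enumeration oracles for the Mk2 model
# ---------------------------------------------------------------------------

def enum_likelihood(tree: Phylogeny, pattern: PhyleticPattern,
                    rates: MkRates, prior=(0.5, 0.5)) -> float:
    """Likelihood by brute-force sum over all internal-state assignments."""
    internals = tree.internal_nodes()
    total = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        states = dict(zip(map(id, internals), assignment))
        for leaf in tree.leaves():
            states[id(leaf)] = pattern[leaf.label]
        p = prior[states[id(tree.root)]]
        for node in tree.postorder():
            if node.parent is None:
                continue
            P = transition_matrix(rates, node.length)
            p *= P[states[id(node.parent)], states[id(node)]]
        total += p
    return total


def enum_log_likelihood(tree, pattern, rates, prior=(0.5, 0.5)) -> float:
    return math.log(enum_likelihood(tree, pattern, rates, prior))


def enum_marginals(tree: Phylogeny, pattern: PhyleticPattern,
                   rates: MkRates, prior=(0.5, 0.5)):
    """Per-internal-node marginals by enumerating joint assignments."""
    internals = tree.internal_nodes()
    acc = {id(n): np.zeros(2) for n in internals}
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        states = dict(zip(map(id, internals), assignment))
        for leaf in tree.leaves():
            states[id(leaf)] = pattern[leaf.label]
        p = prior[states[id(tree.root)]]
        for node in tree.postorder():
            if node.parent is None:
                continue
            P = transition_matrix(rates, node.length)
            p *= P[states[id(node.parent)], states[id(node)]]
        for n in internals:
            acc[id(n)][states[id(n)]] += p
    out = {}
    for n in internals:
        v = acc[id(n)]
        out[id(n)] = v / v.sum()
    return out


# ---------------------------------------------------------------------------
# Exhaustive small-parsimony oracle for pairwise incompatibility
# ---------------------------------------------------------------------------

def _all_unrooted_topologies(n: int):
    """All unrooted binary topologies on taxa 0..n-1, each given as a list
    of edges over nodes (taxa 0..n-1, internal nodes >= n)."""
    assert 3 <= n <= 6
    trees = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                mid = max(max(e) for e in edges) + 1
                new = edges[:k] + edges[k + 1:]
                new += [(u, mid), (mid, v), (leaf, mid)]
                new_trees.append(new)
        trees = new_trees
    return trees


def _fitch_length(edges, tip_states: dict[int, int]) -> int:
    """Minimum number of changes for one site on one topology (Fitch on an
    arbitrary rooting)."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = next(iter(tip_states))
    changes = 0
    sets: dict[int, frozenset] = {}

    order: list[tuple[int, int | None]] = []
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    for node, parent in reversed(order):
        kids = [nb for nb in adj[node] if nb != parent]
        if node in tip_states:
            s = frozenset([tip_states[node]])
            for k in kids:  # rooted at a tip: fold children in anyway
                inter = s & sets[k]
                if inter:
                    s = inter
                else:
                    s = s | sets[k]
                    changes += 1
            sets[node] = s
        else:
            s = None
            for k in kids:
                if s is None:
                    s = sets[k]
                    continue
                inter = s & sets[k]
                if inter:
                    s = inter
                else:
                    s = s | sets[k]
                    changes += 1
            sets[node] = s
    return changes


def parsimony_pair_score(col_i, col_j) -> int:
    """min over all unrooted topologies of (fitch_i + fitch_j)
    - (s_i - 1) - (s_j - 1): the minimum extra changes the pair forces."""
    col_i = list(col_i)
    col_j = list(col_j)
    n = len(col_i)
    s_i = len(set(col_i))
    s_j = len(set(col_j))
    best = None
    for edges in _all_unrooted_topologies(n):
        tips_i = {t: col_i[t] for t in range(n)}
        tips_j = {t: col_j[t] for t in range(n)}
        score = _fitch_length(edges, tips_i) + _fitch_length(edges, tips_j)
        best = score if best is None else min(best, score)
    return best - (s_i - 1) - (s_j - 1)


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def study_tree():
    from intron_turnover.synthetic_data import simulate_yule_tree

    return simulate_yule_tree(29, seed=1, total_length=3.0)
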