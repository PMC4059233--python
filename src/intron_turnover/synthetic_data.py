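"""Simulators matching the generative assumptions of the analysis.

Everything downstream is testable without external data because each stage
has a generator with the right statistical structure:

* Yule (pure-birth) trees, optionally rescaled to a target total branch
  length so simulated datasets match the evolutionary depth of the yeast
  study system (a 29-taxon tree with total length around 3 substitutions
  per site);
* binary presence/absence traits under the two-state gain/loss CTMC,
  returning tip patterns *and* the true internal states;
* clonal nucleotide alignments under Jukes–Cantor;
* gene-conversion mosaics: donor tracts with geometric lengths pasted into
  a recipient row, with the merged/clipped tract list returned as ground
  truth;
* a study-shaped fixture generator — 29 taxa, 22 intron-present, a HEG
  character defined on exactly the intron-present taxa.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mk2_model import MkRates, transition_matrix
from .phylo_io import Alignment, Phylogeny, PhyleticPattern, TreeNode

_NUC = "ACGT"


@dataclass
class TraitSimulation:
    pattern: PhyleticPattern
    internal_states: dict[str, int]
    rates: MkRates
    seed: int | None


@dataclass
class ConversionTract:
    recipient: str
    donor: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_tips: int,
    seed: int | None = None,
    total_length: float | None = None,
    birth_rate: float = 1.0,
) -> Phylogeny:
    """Pure-birth tree with exponential inter-speciation waits.

    Leaves are labelled ``t1..tN`` (in tree traversal order). If
    ``total_length`` is given, all branches are rescaled so their sum hits
    it exactly.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    while True:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.length += wait
        if k == n_tips:
            break
        idx = rng.integers(k)
        split = active.pop(idx)
        active.append(split.add_child(TreeNode()))
        active.append(split.add_child(TreeNode()))
    tree_tmp = Phylogeny.__new__(Phylogeny)
    tree_tmp.root = root
    for i, node in enumerate(
        n for n in tree_tmp.postorder() if n.is_leaf
    ):
        node.label = f"t{i + 1}"
    if total_length is not None:
        current = sum(n.length for n in tree_tmp.postorder() if n.parent is not None)
        factor = total_length / current
        for node in tree_tmp.postorder():
            if node.parent is not None:
                node.length *= factor
    return Phylogeny(root)


def simulate_two_clade_tree(
    n_per_clade: int = 6,
    clade_length: float = 0.15,
    bridge: float = 0.02,
    seed: int | None = None,
) -> Phylogeny:
    """Two shallow Yule clades joined by a bridge branch.

    This is the geometry in which gene conversion between lineages is both
    realistic and detectable: within-clade divergence is small (a few
    percent, like conspecific intron copies) while a cross-clade
    donor/recipient pair sits at roughly ``2 * mean tip depth + bridge``
    substitutions per site apart (about 10% observed divergence at the
    defaults). Leaves are ``t1..tN`` with the first ``n_per_clade`` in
    clade A.
    """
    rng = np.random.default_rng(seed)
    a = simulate_yule_tree(
        n_per_clade, seed=int(rng.integers(2**31)), total_length=clade_length)
    b = simulate_yule_tree(
        n_per_clade, seed=int(rng.integers(2**31)), total_length=clade_length)
    for i, leaf in enumerate(b.leaves()):
        leaf.label = f"t{n_per_clade + i + 1}"
    root = TreeNode()
    a.root.length = bridge / 2
    b.root.length = bridge / 2
    root.add_child(a.root)
    root.add_child(b.root)
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# Binary traits
# ---------------------------------------------------------------------------

def simulate_trait(
    tree: Phylogeny,
    rates: MkRates,
    root_prior: tuple[float, float] = (0.5, 0.5),
    seed: int | None = None,
    character: str = "trait",
) -> TraitSimulation:
    """Realize the two-state CTMC down the tree; root state drawn from
    ``root_prior``, each branch transitioning via P(t)."""
    rng = np.random.default_rng(seed)
    ids = tree.node_ids()
    states: dict[TreeNode, int] = {
        tree.root: int(rng.random() < root_prior[1])
    }
    tips: dict[str, int] = {}
    internal: dict[str, int] = {}
    for node in tree.preorder():
        s = states[node]
        if node.is_leaf:
            tips[node.label] = s
        else:
            internal[ids[node]] = s
        for child in node.children:
            P = transition_matrix(rates, child.length)
            states[child] = int(rng.random() < P[s, 1])
    return TraitSimulation(
        pattern=PhyleticPattern(character=character, states=tips),
        internal_states=internal, rates=rates, seed=seed,
    )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _jc69_evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes–Cantor branch: each site changes with probability
    3/4 (1 - e^{-4t/3}), uniformly to one of the three other bases."""
    p_change = 0.75 * -np.expm1(-4.0 * t / 3.0)
    out = seq.copy()
    hit = rng.random(len(seq)) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        # uniform among the 3 alternatives via an offset 1..3 mod 4
        out[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def simulate_alignment(
    tree: Phylogeny,
    length: int,
    seed: int | None = None,
) -> Alignment:
    """Clonal alignment: i.i.d. uniform root sites evolved by JC69 along
    every branch; one row per leaf."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seqs: dict[TreeNode, np.ndarray] = {
        tree.root: rng.integers(0, 4, size=length)
    }
    labels: list[str] = []
    rows: list[str] = []
    for node in tree.preorder():
        for child in node.children:
            seqs[child] = _jc69_evolve(seqs[node], child.length, rng)
        if node.is_leaf:
            labels.append(node.label)
            rows.append("".join(_NUC[b] for b in seqs[node]))
        del seqs[node]
    return Alignment(labels=labels, sequences=rows)


def evolve_sequence(
    sequence: str, distance: float, seed: int | None = None
) -> str:
    """JC69-evolve a single sequence by a given branch length — convenient
    for manufacturing a donor at a controlled divergence."""
    rng = np.random.default_rng(seed)
    codes = np.array([_NUC.index(c) for c in sequence.upper()])
    return "".join(_NUC[b] for b in _jc69_evolve(codes, distance, rng))


# ---------------------------------------------------------------------------
# Gene conversion
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def apply_conversion(
    aln: Alignment,
    recipient: str,
    donor: str,
    n_tracts: int,
    mean_tract_len: float,
    seed: int | None = None,
) -> tuple[Alignment, list[ConversionTract]]:
    """Paste donor-derived conversion tracts into the recipient row.

    Tract starts are uniform over the alignment; lengths are geometric with
    the given mean (the minimal standard model for conversion-tract length),
    clipped to the alignment bounds; overlapping tracts merge. The returned
    tract list is the post-merge ground truth.
    """
    if recipient == donor:
        raise ValueError("recipient and donor must differ")
    if n_tracts < 0:
        raise ValueError("n_tracts must be >= 0")
    rec = aln.row(recipient)
    don = aln.row(donor)
    L = aln.n_columns
    rng = np.random.default_rng(seed)
    ivals: list[tuple[int, int]] = []
    for _ in range(n_tracts):
        start = int(rng.integers(0, L))
        tract_len = int(rng.geometric(1.0 / mean_tract_len))
        end = min(start + tract_len, L)
        ivals.append((start, end))
    merged = _merge_intervals(ivals)
    chars = list(rec)
    for s, e in merged:
        chars[s:e] = don[s:e]
    new_aln = aln.replace_row(recipient, "".join(chars))
    tracts = [
        ConversionTract(recipient=recipient, donor=donor, start=s, end=e)
        for s, e in merged
    ]
    return new_aln, tracts


# ---------------------------------------------------------------------------
# Study-shaped fixture
# ---------------------------------------------------------------------------

def make_study_fixture(
    seed: int | None = None,
    n_taxa: int = 29,
    n_intron_present: int = 22,
    mu_intron: float = 3.51,
    mu_heg: float = 21.88,
    total_length: float = 3.0,
    max_tries: int = 10_000,
) -> tuple[Phylogeny, PhyleticPattern, PhyleticPattern]:
    """Simulated dataset with the shape of the yeast intron/HEG study:
    29 taxa, 22 intron-present, and a HEG character defined on exactly the
    intron-present taxa (both HEG states represented, so the character is
    informative). Traits are CTMC realizations at the default turnover
    rates; patterns are rejection-sampled until the marginal counts match.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(
        n_taxa, seed=int(rng.integers(2**31)), total_length=total_length)

    intron = None
    for _ in range(max_tries):
        sim = simulate_trait(
            tree, MkRates.er(mu_intron), seed=int(rng.integers(2**31)),
            character="intron")
        if sum(sim.pattern.states.values()) == n_intron_present:
            intron = sim.pattern
            break
    if intron is None:
        raise RuntimeError(
            f"could not hit {n_intron_present}/{n_taxa} present in "
            f"{max_tries} tries")

    present_taxa = {t for t, s in intron.states.items() if s == 1}
    heg = None
    for _ in range(max_tries):
        sim = simulate_trait(
            tree, MkRates.er(mu_heg), seed=int(rng.integers(2**31)),
            character="heg")
        sub = {t: s for t, s in sim.pattern.states.items() if t in present_taxa}
        if 0 < sum(sub.values()) < len(sub):
            heg = PhyleticPattern(character="heg", states=sub)
            break
    if heg is None:
        raise RuntimeError("could not produce a dimorphic HEG pattern")
    return tree, intron, heg
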