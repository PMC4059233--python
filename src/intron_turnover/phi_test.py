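"""Pairwise homoplasy index (PHI) test for recombination, from first principles.

Recombination (here: gene conversion between intron/HEG copies of different
origin) leaves a spatial signature in an alignment: sites that are physically
close share a genealogy more often than distant sites, so close pairs of
parsimony-informative sites tend to be *compatible* (jointly explainable on
one tree with no extra changes) while distant pairs are not. The PHI
statistic is the mean "refined incompatibility" score over nearby pairs of
informative sites; a value lower than expected under random site order is
evidence of recombination.

The refined incompatibility of two sites is the minimum number of extra
state changes (homoplasies) the pair jointly forces on *any* tree. For sites
i and j scored over the taxa non-missing at both, it equals the cyclomatic
number of the bipartite "joint state" graph (states of i and of j as
vertices, observed joint pairs as edges):

    l(i, j) = o - s_i - s_j + c

with o the number of distinct joint pairs, s_i/s_j the per-site state
counts, and c the number of connected components. l = 0 iff the two sites
are compatible (the classic four-gamete test is the binary special case).

Significance comes from permuting the assignment of informative-site columns
to their positions (column contents intact): under clonality the statistic
is exchangeable over orderings, under recombination the observed ordering is
atypically compatible at short range, so *small* observed values are
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .phylo_io import Alignment

#: sentinel for a pair that cannot be scored (fewer than 2 jointly
#: non-missing taxa)
UNDEFINED = -1


@dataclass
class SiteColumn:
    """One alignment column restricted to the PHI state convention:
    nucleotide codes 0..3; gaps and ambiguity codes are missing (-1)."""

    index: int
    states: np.ndarray  # int8 over taxa, -1 = missing

    @property
    def observed_states(self) -> set[int]:
        return set(int(s) for s in self.states if s >= 0)


@dataclass
class PhiResult:
    statistic: float | None
    window: int
    k_informative: int
    n_pairs: int
    skipped_pairs: int
    permutations: int
    p_permutation: float | None
    p_normal: float | None
    seed: int | None
    defined: bool
    reason: str = ""


def site_columns(aln: Alignment) -> np.ndarray:
    """(n_taxa, n_columns) int8 matrix in PHI convention (missing = -1)."""
    codes = aln.codes().astype(np.int8)
    codes[codes >= 4] = -1  # gap and ambiguity both count as missing
    return codes


def informative_sites(aln: Alignment) -> list[SiteColumn]:
    """Parsimony-informative columns, in alignment order.

    A column qualifies when at least two distinct non-missing states each
    occur in at least two taxa.
    """
    codes = site_columns(aln)
    out: list[SiteColumn] = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        vals, counts = np.unique(col[col >= 0], return_counts=True)
        if (counts >= 2).sum() >= 2:
            out.append(SiteColumn(index=j, states=col.copy()))
    return out


def refined_incompatibility(site_i: SiteColumn, site_j: SiteColumn) -> int:
    """Minimum number of extra changes sites i and j jointly force on any
    tree (0 iff compatible). Scored over taxa non-missing at both sites;
    raises if fewer than 2 such taxa remain."""
    a = site_i.states
    b = site_j.states
    mask = (a >= 0) & (b >= 0)
    if int(mask.sum()) < 2:
        raise ValueError("fewer than 2 taxa jointly non-missing")
    pairs = set(zip(a[mask].tolist(), b[mask].tolist()))
    left = {p[0] for p in pairs}
    right = {p[1] for p in pairs}
    # connected components of the bipartite state graph via union-find
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in left:
        parent[("L", s)] = ("L", s)
    for s in right:
        parent[("R", s)] = ("R", s)
    for u, v in pairs:
        ru, rv = find(("L", u)), find(("R", v))
        if ru != rv:
            parent[ru] = rv
    components = len({find(x) for x in parent})
    return len(pairs) - len(left) - len(right) + components


@njit(cache=False)
def _pair_scores(cols: np.ndarray) -> np.ndarray:  # pragma: no cover - jit
    """All-pairs refined incompatibility over informative columns.

    cols: (k, n_taxa) int8, missing = -1. Returns (k, k) int16 with
    UNDEFINED where fewer than 2 taxa are jointly non-missing.
    """
    k, n = cols.shape
    out = np.zeros((k, k), dtype=np.int16)
    # scratch structures for the tiny bipartite graph (<= 4 states per side)
    parent = np.empty(8, dtype=np.int8)
    for i in range(k):
        for j in range(i + 1, k):
            seen_pairs = np.zeros((4, 4), dtype=np.int8)
            left = np.zeros(4, dtype=np.int8)
            right = np.zeros(4, dtype=np.int8)
            n_joint = 0
            o = 0
            for t in range(n):
                a = cols[i, t]
                b = cols[j, t]
                if a < 0 or b < 0:
                    continue
                n_joint += 1
                if seen_pairs[a, b] == 0:
                    seen_pairs[a, b] = 1
                    o += 1
                left[a] = 1
                right[b] = 1
            if n_joint < 2:
                out[i, j] = UNDEFINED
                out[j, i] = UNDEFINED
                continue
            si = 0
            sj = 0
            for s in range(4):
                si += left[s]
                sj += right[s]
            # union-find over 8 possible vertices: 0..3 left, 4..7 right
            for v in range(8):
                parent[v] = v
            for a in range(4):
                for b in range(4):
                    if seen_pairs[a, b] == 1:
                        ra = a
                        while parent[ra] != ra:
                            ra = parent[ra]
                        rb = 4 + b
                        while parent[rb] != rb:
                            rb = parent[rb]
                        if ra != rb:
                            parent[ra] = rb
            c = 0
            for s in range(4):
                if left[s] == 1 and parent[s] == s:
                    c += 1
                if right[s] == 1 and parent[4 + s] == 4 + s:
                    c += 1
            # roots of merged components may sit on either side; count roots
            # among *used* vertices only
            # (the loop above already did exactly that)
            score = o - si - sj + c
            out[i, j] = score
            out[j, i] = score
    return out


def pair_score_matrix(sites: list[SiteColumn]) -> np.ndarray:
    """(k, k) matrix of refined incompatibilities (UNDEFINED = unscorable)."""
    if not sites:
        return np.zeros((0, 0), dtype=np.int16)
    cols = np.stack([s.states for s in sites]).astype(np.int8)
    return _pair_scores(cols)


def _mean_score(scores: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> tuple[float | None, int, int]:
    vals = scores[ii, jj]
    ok = vals != UNDEFINED
    n_ok = int(ok.sum())
    skipped = int((~ok).sum())
    if n_ok == 0:
        return None, 0, skipped
    return float(vals[ok].mean()), n_ok, skipped


def phi(
    aln: Alignment,
    window: int = 100,
    permutations: int = 1000,
    seed: int | None = None,
    normal_approx: bool = False,
    distance: str = "alignment",
) -> PhiResult:
    """PHI recombination test.

    Parameters
    ----------
    window:
        Pairs of informative sites at most this far apart contribute to the
        statistic. ``distance="alignment"`` (default) measures the gap in
        alignment columns; ``distance="rank"`` measures it in informative-
        site rank.
    permutations:
        Number of random site-order permutations for the null distribution.
    normal_approx:
        Additionally report a p-value from a normal fit to the permutation
        replicates.

    Notes
    -----
    Small observed statistics are significant (recombination makes nearby
    pairs *more* compatible); the permutation p-value uses the add-one
    estimator so it is never exactly zero.
    """
    if distance not in ("alignment", "rank"):
        raise ValueError(f"unknown distance mode {distance!r}")
    sites = informative_sites(aln)
    k = len(sites)
    base = PhiResult(
        statistic=None, window=window, k_informative=k, n_pairs=0,
        skipped_pairs=0, permutations=permutations, p_permutation=None,
        p_normal=None, seed=seed, defined=False,
    )
    if k < 2:
        base.reason = f"only {k} informative site(s); test undefined"
        return base

    positions = np.array(
        [s.index for s in sites] if distance == "alignment" else range(k)
    )
    iu, ju = np.triu_indices(k, 1)
    near = (positions[ju] - positions[iu]) <= window
    ii, jj = iu[near], ju[near]
    if len(ii) == 0:
        base.reason = "no informative-site pair within the window"
        return base

    scores = pair_score_matrix(sites)
    obs, n_pairs, skipped = _mean_score(scores, ii, jj)
    if obs is None:
        base.reason = "all nearby pairs unscorable (missing data)"
        return base

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(permutations)
    for b in range(permutations):
        sigma = rng.permutation(k)
        val, _, _ = _mean_score(scores, sigma[ii], sigma[jj])
        perm_stats[b] = np.nan if val is None else val
    valid = perm_stats[~np.isnan(perm_stats)]
    n_valid = len(valid)
    if n_valid == 0:
        base.reason = "no valid permutation replicate"
        return base
    p_perm = (1 + int((valid <= obs + 1e-12).sum())) / (1 + n_valid)

    p_norm = None
    if normal_approx:
        m, sd = float(valid.mean()), float(valid.std(ddof=1))
        if sd > 0:
            from scipy.stats import norm

            p_norm = float(norm.cdf((obs - m) / sd))
        else:
            p_norm = 1.0
    return PhiResult(
        statistic=obs, window=window, k_informative=k, n_pairs=n_pairs,
        skipped_pairs=skipped, permutations=n_valid,
        p_permutation=float(p_perm), p_normal=p_norm, seed=seed, defined=True,
    )
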