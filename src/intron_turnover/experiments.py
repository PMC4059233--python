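"""Reusable simulation experiments: calibration, power and recovery studies.

These are the quantitative checks of the whole pipeline — parameter
recovery of the turnover rate, type-I error and power of the PHI test, and
breakpoint recovery of the mosaic scanner — expressed as plain functions so
the analysis drivers, the test suite and the reproduction script all run
exactly the same computation.

Every experiment takes an explicit seed and derives per-replicate seeds
from a single generator, so results are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mk2_model import MkRates, fit
from .mosaic_scan import call_segments, donor_runs, window_identity
from .phi_test import phi
from .phylo_io import Alignment
from .synthetic_data import (
    apply_conversion,
    evolve_sequence,
    simulate_alignment,
    simulate_trait,
    simulate_two_clade_tree,
    simulate_yule_tree,
)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


@dataclass
class RecoveryResult:
    estimates: list[float]
    median: float
    true_mu: float
    n_boundary: int
    ard_never_below_er: bool
    coverage: float  # fraction of Wald 95% intervals covering the truth


def turnover_recovery(
    n_replicates: int = 200,
    true_mu: float = 3.5,
    n_taxa: int = 29,
    total_length: float = 3.0,
    seed: int = 1,
    check_ard: bool = True,
) -> RecoveryResult:
    """Simulate presence/absence patterns at a known turnover rate on one
    Yule tree and re-estimate the rate from each pattern.

    The median estimate is the headline: single-pattern turnover estimates
    are noisy (the study's own standard errors are about half the estimate
    for the intron and three quarters for the HEG), but the estimator is
    consistent, so the median over replicates should sit near the truth.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_taxa, seed=_child_seed(rng),
                              total_length=total_length)
    estimates: list[float] = []
    n_boundary = 0
    ard_ok = True
    covered = 0
    n_with_se = 0
    for _ in range(n_replicates):
        sim = simulate_trait(tree, MkRates.er(true_mu), seed=_child_seed(rng))
        er = fit(tree, sim.pattern, model="ER")
        if er.boundary:
            n_boundary += 1
        else:
            estimates.append(er.mu)
            if er.se["mu"] is not None:
                n_with_se += 1
                half = 1.96 * er.se["mu"]
                if er.mu - half <= true_mu <= er.mu + half:
                    covered += 1
        if check_ard:
            ard = fit(tree, sim.pattern, model="ARD")
            if ard.lnl < er.lnl - 1e-8:
                ard_ok = False
    return RecoveryResult(
        estimates=estimates,
        median=float(np.median(estimates)) if estimates else float("nan"),
        true_mu=true_mu,
        n_boundary=n_boundary,
        ard_never_below_er=ard_ok,
        coverage=covered / n_with_se if n_with_se else float("nan"),
    )


def phi_type_i_error(
    n_replicates: int = 200,
    n_taxa: int = 29,
    length: int = 1500,
    total_length: float = 3.0,
    window: int = 100,
    permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 2,
) -> float:
    """Rejection rate of the PHI test on clonal (recombination-free)
    alignments simulated on one Yule tree; should sit near alpha."""
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_taxa, seed=_child_seed(rng),
                              total_length=total_length)
    rejections = 0
    for _ in range(n_replicates):
        aln = simulate_alignment(tree, length, seed=_child_seed(rng))
        res = phi(aln, window=window, permutations=permutations,
                  seed=_child_seed(rng))
        if res.defined and res.p_permutation < alpha:
            rejections += 1
    return rejections / n_replicates


def phi_power(
    n_replicates: int = 100,
    n_per_clade: int = 6,
    clade_length: float = 0.15,
    bridge: float = 0.02,
    length: int = 1500,
    n_tracts: int = 5,
    mean_tract_len: float = 150.0,
    window: int = 100,
    permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 3,
) -> tuple[float, float]:
    """Rejection rate on gene-conversion mosaics, plus the mean observed
    donor/recipient divergence.

    The panel is two shallow clades (conspecific-like intron copies) joined
    by a bridge; the donor sits in the opposite clade from the recipient at
    roughly 10% observed divergence under the defaults, and conversion
    tracts pasted across the clades create the locally conflicting
    genealogies PHI is built to detect.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    divergences = []
    recipient = "t1"
    donor = f"t{n_per_clade + 1}"
    for _ in range(n_replicates):
        tree = simulate_two_clade_tree(
            n_per_clade, clade_length, bridge, seed=_child_seed(rng))
        aln = simulate_alignment(tree, length, seed=_child_seed(rng))
        x = np.frombuffer(aln.row(recipient).encode(), dtype=np.uint8)
        y = np.frombuffer(aln.row(donor).encode(), dtype=np.uint8)
        divergences.append(float((x != y).mean()))
        mosaic, _ = apply_conversion(
            aln, recipient, donor, n_tracts, mean_tract_len,
            seed=_child_seed(rng))
        res = phi(mosaic, window=window, permutations=permutations,
                  seed=_child_seed(rng))
        if res.defined and res.p_permutation < alpha:
            rejections += 1
    return rejections / n_replicates, float(np.mean(divergences))


def mosaic_breakpoint_recovery(
    n_replicates: int = 50,
    length: int = 1200,
    donor_distance: float = 0.245,
    window: int = 50,
    step: int = 10,
    max_tract: int = 300,
    seed: int = 4,
) -> float:
    """Fraction of planted conversion tracts whose two breakpoints the
    scanner recovers within window - step columns.

    Each chimera splices one donor-B tract (length between 2x window and
    ``max_tract``) into a donor-A backbone, with A and B separated by
    ``donor_distance`` substitutions per site (about 20% observed
    divergence at the default — the cross-genus regime in which mosaic
    introns are diagnosed). Breakpoint resolution is limited by the local
    spacing of discriminating columns, roughly 1/divergence, so at much
    lower divergence the boundaries genuinely blur."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        backbone_rng = np.random.default_rng(_child_seed(rng))
        a = "".join(backbone_rng.choice(list("ACGT"), length))
        b = evolve_sequence(a, donor_distance, seed=_child_seed(rng))
        start = int(rng.integers(2 * window, length - 2 * window - max_tract))
        end = start + int(rng.integers(2 * window, max_tract))
        query = a[:start] + b[start:end] + a[end:]
        aln = Alignment(labels=["query", "A", "B"], sequences=[query, a, b])
        profile = window_identity(aln, "query", ["A", "B"],
                                  window=window, step=step)
        spans = donor_runs(call_segments(profile), "B")
        tol = window - step
        if any(abs(s - start) <= tol and abs(e - end) <= tol
               for s, e in spans):
            hits += 1
    return hits / n_replicates
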