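"""Two-state continuous-time Markov (Mk2) machinery for presence/absence traits.

A character (intron present/absent, or HEG present/absent within the intron)
evolves along a phylogeny under a CTMC on states {0 (absence), 1 (presence)}
with gain rate alpha (0->1) and loss rate beta (1->0). Branch lengths are in
expected nucleotide substitutions per site, so fitted rates are *turnover
rates relative to substitution*: mu = 1 means the character is gained/lost
as fast as an average nucleotide substitutes.

The module provides:

* the closed-form transition matrix P(t);
* the pruning (post-order dynamic-programming) log-likelihood of a tip
  pattern, with per-node rescaling for numerical safety;
* maximum-likelihood fitting of the equal-rates (ER, alpha=beta=mu) and
  all-rates-different (ARD) models, with observed-information standard
  errors;
* fixed-rate likelihoods, likelihood surfaces over a rate grid, and
  chi-square likelihood-ratio tests between hypotheses;
* marginal (two-pass) ancestral state reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo_io import Phylogeny, PhyleticPattern, TreeNode

LOG_RATE_LO = math.log(1e-6)
LOG_RATE_HI = math.log(1e4)

FLAT_PRIOR = (0.5, 0.5)


@dataclass(frozen=True)
class MkRates:
    """Gain (0->1) and loss (1->0) rates per unit branch length."""

    gain: float
    loss: float
    model: Literal["ER", "ARD"] = "ARD"

    def __post_init__(self) -> None:
        if not (self.gain > 0 and self.loss > 0):
            raise ValueError("rates must be strictly positive")
        if not (np.isfinite(self.gain) and np.isfinite(self.loss)):
            raise ValueError("rates must be finite")
        if self.model == "ER" and self.gain != self.loss:
            raise ValueError("ER model requires gain == loss")

    @classmethod
    def er(cls, mu: float) -> "MkRates":
        return cls(gain=mu, loss=mu, model="ER")

    @classmethod
    def ard(cls, gain: float, loss: float) -> "MkRates":
        return cls(gain=gain, loss=loss, model="ARD")

    @property
    def stationary(self) -> tuple[float, float]:
        s = self.gain + self.loss
        return (self.loss / s, self.gain / s)


@dataclass
class MkFit:
    rates: MkRates
    lnl: float
    se: dict[str, float | None]
    converged: bool
    iterations: int
    boundary: bool
    root_prior: tuple[float, float]

    @property
    def mu(self) -> float:
        """Turnover rate; only meaningful for ER fits."""
        if self.rates.model != "ER":
            raise ValueError("mu is defined for ER fits only")
        return self.rates.gain


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    lnl_a: float
    lnl_b: float
    description: str = ""


@dataclass
class LikelihoodSurface:
    grid: np.ndarray
    lnl: np.ndarray
    argmax: int

    @property
    def mu_at_max(self) -> float:
        return float(self.grid[self.argmax])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.grid, "lnl": self.lnl})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class AncestralReconstruction:
    """Marginal posterior P(state) per internal node under the model."""

    probs: dict[TreeNode, tuple[float, float]]
    node_ids: dict[TreeNode, str]
    rates: MkRates
    root_prior: tuple[float, float]

    def table(self) -> pd.DataFrame:
        rows = [
            {"node": self.node_ids[n], "p_absent": p0, "p_present": p1}
            for n, (p0, p1) in self.probs.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transition matrix and pruning likelihood
# ---------------------------------------------------------------------------

def transition_matrix(rates: MkRates, t: float) -> np.ndarray:
    """Closed-form P(t) for the two-state chain.

    P01(t) = a/(a+b) (1 - e^{-(a+b)t}),  P10(t) = b/(a+b) (1 - e^{-(a+b)t});
    diagonals are the complements. Rows sum to 1 exactly up to rounding.
    """
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    a, b = rates.gain, rates.loss
    s = a + b
    # -expm1 is (1 - e^{-st}) without cancellation for small st
    w = -math.expm1(-s * t)
    p01 = a / s * w
    p10 = b / s * w
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def _branch_matrices(tree: Phylogeny, rates: MkRates) -> dict[TreeNode, np.ndarray]:
    # memoize by branch length: trees reuse a handful of distinct lengths
    cache: dict[float, np.ndarray] = {}
    out: dict[TreeNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        P = cache.get(node.length)
        if P is None:
            P = transition_matrix(rates, node.length)
            cache[node.length] = P
        out[node] = P
    return out


def _up_conditionals(
    tree: Phylogeny,
    pattern: PhyleticPattern,
    P: dict[TreeNode, np.ndarray],
) -> tuple[dict[TreeNode, np.ndarray], float]:
    """Post-order conditional likelihood vectors with rescaling.

    Returns (L, log_scale) where L[v][s] is proportional to
    P(tip data below v | state s at v) and log_scale accumulates the
    normalization pulled out at each internal node.
    """
    L: dict[TreeNode, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            state = pattern[node.label]
            vec = np.zeros(2)
            vec[state] = 1.0
            L[node] = vec
        else:
            vec = np.ones(2)
            for child in node.children:
                vec = vec * (P[child] @ L[child])
            m = vec.max()
            if m <= 0:
                # impossible pattern (cannot occur with positive rates)
                L[node] = vec
                continue
            L[node] = vec / m
            log_scale += math.log(m)
    return L, log_scale


def log_likelihood(
    tree: Phylogeny,
    pattern: PhyleticPattern,
    rates: MkRates,
    root_prior: Sequence[float] = FLAT_PRIOR,
) -> float:
    """Pruning log-likelihood of a tip pattern under the Mk2 model."""
    pattern.validate_against(tree)
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (2,) or not math.isclose(prior.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("root_prior must be two probabilities summing to 1")
    P = _branch_matrices(tree, rates)
    L, log_scale = _up_conditionals(tree, pattern, P)
    lik = float(prior @ L[tree.root])
    if lik <= 0:
        return -math.inf
    return math.log(lik) + log_scale


def loglik_at_rate(
    tree: Phylogeny,
    pattern: PhyleticPattern,
    mu: float,
    root_prior: Sequence[float] = FLAT_PRIOR,
) -> float:
    """ER log-likelihood at a fixed turnover rate (flat root prior)."""
    return log_likelihood(tree, pattern, MkRates.er(mu), root_prior)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

_BOUND_TOL = 1e-3  # log-scale distance below which an optimum counts as boundary


def _resolve_prior(root: str, rates: MkRates) -> tuple[float, float]:
    if root == "flat":
        return FLAT_PRIOR
    if root == "stationary":
        return rates.stationary
    raise ValueError(f"unknown root prior {root!r}")


def _hessian_diag_se(f, x0: np.ndarray, h: float = 1e-4) -> list[float | None]:
    """Delta-method SEs from the observed information of lnL in log-rate
    coordinates. Returns one SE per coordinate (None if curvature is not
    negative definite)."""
    k = len(x0)
    H = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp = x0.copy(); xp[i] += h
                xm = x0.copy(); xm[i] -= h
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h**2
            else:
                xpp = x0.copy(); xpp[[i, j]] += h
                xmm = x0.copy(); xmm[[i, j]] -= h
                xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
                xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h**2)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return [None] * k
    ses: list[float | None] = []
    for i in range(k):
        v = cov[i, i]
        if v <= 0 or not np.isfinite(v):
            ses.append(None)
        else:
            # delta method: SE(rate) = rate * SE(log rate)
            ses.append(float(math.exp(x0[i]) * math.sqrt(v)))
    return ses


def fit(
    tree: Phylogeny,
    pattern: PhyleticPattern,
    model: Literal["ER", "ARD"] = "ER",
    root: str = "flat",
) -> MkFit:
    """Maximum-likelihood rate estimation.

    ER: bounded 1-D search on log(mu); ARD: Nelder–Mead on (log gain,
    log loss), started from the ER optimum so the ARD likelihood can never
    fall below the ER one. Standard errors come from the finite-difference
    observed information at the optimum; monomorphic patterns drive mu to
    the search boundary, which is flagged rather than raised.
    """
    pattern.validate_against(tree)

    if model == "ER":
        def neg(logmu: float) -> float:
            rates = MkRates.er(math.exp(logmu))
            prior = _resolve_prior(root, rates)
            return -log_likelihood(tree, pattern, rates, prior)

        res = optimize.minimize_scalar(
            neg, bounds=(LOG_RATE_LO, LOG_RATE_HI), method="bounded",
            options={"xatol": 1e-10},
        )
        logmu = float(res.x)
        boundary = (
            logmu - LOG_RATE_LO < _BOUND_TOL or LOG_RATE_HI - logmu < _BOUND_TOL
        )
        rates = MkRates.er(math.exp(logmu))
        prior = _resolve_prior(root, rates)
        lnl = -float(res.fun)
        if boundary:
            se: dict[str, float | None] = {"mu": None}
        else:
            (se_mu,) = _hessian_diag_se(lambda x: -neg(x[0]), np.array([logmu]))
            se = {"mu": se_mu}
        return MkFit(
            rates=rates, lnl=lnl, se=se,
            converged=bool(res.success), iterations=int(res.nfev),
            boundary=boundary, root_prior=prior,
        )

    if model == "ARD":
        def neg2(x: np.ndarray) -> float:
            rates = MkRates.ard(math.exp(x[0]), math.exp(x[1]))
            prior = _resolve_prior(root, rates)
            return -log_likelihood(tree, pattern, rates, prior)

        er_fit = fit(tree, pattern, model="ER", root=root)
        x0 = np.log([er_fit.rates.gain, er_fit.rates.loss])
        res = optimize.minimize(
            neg2, x0, method="Nelder-Mead",
            bounds=[(LOG_RATE_LO, LOG_RATE_HI)] * 2,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        x = np.asarray(res.x, dtype=float)
        boundary = bool(
            np.any(x - LOG_RATE_LO < _BOUND_TOL)
            or np.any(LOG_RATE_HI - x < _BOUND_TOL)
        )
        rates = MkRates.ard(math.exp(x[0]), math.exp(x[1]))
        prior = _resolve_prior(root, rates)
        lnl = -float(res.fun)
        if boundary:
            se = {"gain": None, "loss": None}
        else:
            se_gain, se_loss = _hessian_diag_se(lambda y: -neg2(y), x)
            se = {"gain": se_gain, "loss": se_loss}
        return MkFit(
            rates=rates, lnl=lnl, se=se,
            converged=bool(res.success), iterations=int(res.nit),
            boundary=boundary, root_prior=prior,
        )

    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Likelihood-ratio tests and surfaces
# ---------------------------------------------------------------------------

def chi_square_p(statistic: float, df: int = 1) -> float:
    """Upper-tail chi-square probability of a 2*dlnL statistic."""
    if statistic < 0:
        raise ValueError("statistic must be >= 0")
    return float(stats.chi2.sf(statistic, df))


def likelihood_ratio(
    tree: Phylogeny,
    pattern: PhyleticPattern,
    hypothesis_a: float | str,
    hypothesis_b: float | str,
    df: int = 1,
    root: str = "flat",
) -> LRTResult:
    """Likelihood-ratio test between two ER hypotheses.

    Each hypothesis is either a fixed turnover rate or the string ``"ml"``
    (rate estimated by maximum likelihood). The statistic is 2|lnL_A - lnL_B|
    and the p-value the chi-square upper tail at the caller-supplied degrees
    of freedom (default 1).
    """

    def lnl_of(h: float | str) -> float:
        if isinstance(h, str):
            if h.lower() != "ml":
                raise ValueError(f"hypothesis must be a rate or 'ml', got {h!r}")
            return fit(tree, pattern, model="ER", root=root).lnl
        return loglik_at_rate(tree, pattern, float(h))

    lnl_a = lnl_of(hypothesis_a)
    lnl_b = lnl_of(hypothesis_b)
    statistic = 2.0 * abs(lnl_a - lnl_b)
    return LRTResult(
        statistic=statistic, df=df, p_value=chi_square_p(statistic, df),
        lnl_a=lnl_a, lnl_b=lnl_b,
        description=f"{hypothesis_a} vs {hypothesis_b}",
    )


def likelihood_surface(
    tree: Phylogeny,
    pattern: PhyleticPattern,
    grid: Sequence[float],
    root_prior: Sequence[float] = FLAT_PRIOR,
) -> LikelihoodSurface:
    """ER log-likelihood over a strictly increasing grid of turnover rates."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1:
        raise ValueError("grid must be a 1-D sequence of rates")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly positive and increasing")
    lnl = np.array([
        loglik_at_rate(tree, pattern, mu, root_prior) for mu in grid
    ])
    return LikelihoodSurface(grid=grid, lnl=lnl, argmax=int(np.argmax(lnl)))


# ---------------------------------------------------------------------------
# Marginal ancestral reconstruction
# ---------------------------------------------------------------------------

def ancestral_marginals(
    tree: Phylogeny,
    pattern: PhyleticPattern,
    rates: MkRates,
    root_prior: Sequence[float] = FLAT_PRIOR,
) -> AncestralReconstruction:
    """Marginal posterior state probabilities at every internal node.

    Standard two-pass algorithm: the post-order pass collects conditional
    likelihoods of the data below each node; the pre-order pass propagates
    the probability of the data *outside* each node's subtree. The marginal
    at a node is the normalized product of the two.
    """
    pattern.validate_against(tree)
    prior = np.asarray(root_prior, dtype=float)
    P = _branch_matrices(tree, rates)
    L, _ = _up_conditionals(tree, pattern, P)

    # child -> parent messages M_c(s_parent) = sum_s P_c(s_parent, s) L_c(s)
    msg = {node: P[node] @ L[node] for node in P}

    down: dict[TreeNode, np.ndarray] = {tree.root: prior.copy()}
    for node in tree.preorder():
        for child in node.children:
            partial = down[node].copy()
            for sib in node.children:
                if sib is not child:
                    partial = partial * msg[sib]
            vec = P[child].T @ partial
            m = vec.max()
            down[child] = vec / m if m > 0 else vec

    probs: dict[TreeNode, tuple[float, float]] = {}
    for node in tree.internal_nodes():
        joint = down[node] * L[node]
        total = joint.sum()
        if total <= 0:
            raise ValueError("zero marginal likelihood at an internal node")
        p = joint / total
        probs[node] = (float(p[0]), float(p[1]))
    return AncestralReconstruction(
        probs=probs, node_ids=tree.node_ids(), rates=rates,
        root_prior=(float(prior[0]), float(prior[1])),
    )


def annotate_tree_with_marginals(
    tree: Phylogeny, recon: AncestralReconstruction
) -> Phylogeny:
    """Copy of the tree whose internal labels carry P(present) — handy for
    eyeballing reconstructions in any tree viewer."""
    annotated = tree.copy()
    orig = list(tree.preorder())
    copy_nodes = list(annotated.preorder())
    for o, c in zip(orig, copy_nodes):
        if o in recon.probs:
            c.label = f"{recon.probs[o][1]:.4f}"
    return annotated
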