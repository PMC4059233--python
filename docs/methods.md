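# Methods

This package quantifies how fast a mobile genetic element — a group I
intron in the yeast mitochondrial large-subunit rRNA gene, and the homing
endonuclease gene (HEG) it carries — is gained and lost across a clade,
and provides the sequence-level evidence machinery (a recombination test
and a mosaic scanner) for asking *how* those gains and losses happen.
This note records the models, the defaults and why they were chosen, what
the simulators do and do not emulate, and the numerical decisions.

## Turnover model

Presence/absence of a character across the tips of a rooted phylogeny is
modelled as a two-state continuous-time Markov chain with gain rate α
(0→1) and loss rate β (1→0). Branch lengths are expected nucleotide
substitutions per site, so rates are **turnover rates relative to
substitution**: μ = 1 means the character is gained/lost as often as an
average site substitutes. The transition matrix is closed-form,

    P01(t) = α/(α+β)·(1−e^{−(α+β)t}),   P10(t) = β/(α+β)·(1−e^{−(α+β)t}),

with diagonals the complements; `1−e^{−x}` is computed via `expm1` to
avoid cancellation at short branches. The tip-pattern likelihood is the
standard pruning recursion (post-order conditional-likelihood vectors),
with per-node rescaling and accumulated log factors so trees far larger
than the 29-taxon study system cannot underflow.

**Root prior.** Flat (½, ½) by default. Under the equal-rates (ER) model
this *is* the stationary distribution, so the choice is inert for the
headline analyses; for the all-rates-different (ARD) model a
`root="stationary"` option uses (β, α)/(α+β) instead.

**Fitting.** ER: bounded scalar search (Brent) on log μ over
[log 10⁻⁶, log 10⁴]; ARD: Nelder–Mead on (log α, log β) in the same box,
started at the ER optimum — which also guarantees lnL(ARD) ≥ lnL(ER), as
nesting requires. Log-parameterization keeps rates positive with no
penalty terms. An optimum within 10⁻³ (log scale) of a box edge is
flagged `boundary`; monomorphic patterns legitimately produce this (their
likelihood is monotone decreasing in μ) and are reported with the flag
rather than raised, because "turnover close to zero" is itself a
hypothesis of interest here.

**Standard errors.** Observed information: central finite differences of
lnL at the optimum (step 10⁻⁴ on the log scale), inverted and
delta-method-transformed back to the rate scale (SE(μ) = μ·SE(log μ)).
When the curvature is not negative definite — flat likelihood plateaus do
occur, see below — or the optimum is at a bound, the SE is reported
unavailable instead of fabricating a number.

**Likelihood-ratio tests.** 2·|Δln L| compared to the upper χ² tail; the
degrees of freedom are an explicit argument (default 1) because one of
the comparisons of interest — fixed rate vs fixed rate — is not a
textbook nested pair, and the caller should own that choice.

**Saturation plateau.** When μ × (total tree length) is large the chain
equilibrates on every branch, every tip becomes an independent coin flip,
and lnL flattens at n·ln ½. A scattered pattern can then push the ML
estimate arbitrarily high with a huge or undefined SE while a *test
against a small fixed rate remains decisive* — the surface is steep on
the left and flat on the right. The analysis driver for the study-shaped
fixture reproduces exactly this behaviour for the fast (HEG-like)
character, which is why likelihood surfaces (`likelihood_surface`) are a
first-class output rather than a debugging aid.

**Ancestral states.** True two-pass marginals: the post-order pass
collects below-node conditionals, a pre-order pass propagates the
probability of everything outside each node's subtree, and the marginal
is their normalized product. (Single-pass "local" conditionals at a node
are not the same quantity; this package computes the marginals.)

## PHI recombination test

Recombination between diverged copies leaves nearby alignment columns
more *compatible* (jointly explainable on a single tree) than distant
ones. For two parsimony-informative sites scored over the taxa
non-missing at both, the refined incompatibility

    ℓ(i, j) = o − s_i − s_j + c

(o distinct joint state-pairs, s the per-site state counts, c the
connected components of the bipartite joint-state graph) equals the
cyclomatic number of that graph, which is the minimum number of extra
changes any tree must pay for the pair — 0 iff compatible, and the
four-gamete test is the binary special case. This identity is exercised
against an exhaustive small-parsimony oracle (all unrooted topologies on
5–6 taxa) in the test suite. The statistic Φ_w is the mean ℓ over pairs
of informative sites at most w = 100 alignment columns apart (an
informative-site-rank distance is available behind a flag).

Significance: permute the assignment of informative columns to their
positions (contents intact), recompute Φ_w, and report the add-one
estimator p = (1 + #{Φ_perm ≤ Φ_obs})/(1 + B) — *small* observed values
are significant. B = 1000 by default; the all-pairs score matrix is
computed once (numba kernel) so permutations are cheap re-indexing.
Gaps and ambiguity codes are missing data; pairs with fewer than two
jointly scored taxa are skipped and counted. Fewer than two informative
sites yields an explicit "test undefined" result, never a p-value.

**Calibration and power.** On clonal 29-taxon alignments (1500 columns,
JC69, tree total length 3) the measured type-I error at α = 0.05 is
0.045–0.065 across seeds (200 replicates). Power is measured in the
geometry where conversion is both realistic and informative: two shallow
Yule clades (6+6 taxa, within-clade total length 0.15) joined by a short
bridge, donor and recipient in opposite clades at ~10% observed
divergence, five tracts of mean length 150 pasted into the recipient.
Measured power: 0.86–0.94. A deliberately documented negative control:
pasting tracts from an *external* donor into a single recipient produces
only one bipartition among the converted sites — perfectly compatible
data, no signal for any recombination test — so panel geometry, not the
statistic, is what makes conversion detectable.

## Mosaic scanner

Sliding windows (default 50 columns, step 10 — the diagnostic regions in
the motivating system are ~30–90 nt) score the fraction of identical
columns between a query and each candidate donor over columns where both
are non-missing; `count_indels=True` scores gap-vs-base as mismatch
instead. Consecutive windows with identical top-donor sets (ties kept,
never broken arbitrarily — equal proximity to several donors is a
finding, not a nuisance) merge into segments; overlapping windows from
adjacent segments are clipped so segments never overlap. For estimating
a planted or suspected tract span, `donor_runs` takes the maximal run of
donor-containing segments and trims edge segments where the donor is
merely tied: a window straddling a breakpoint has mixed ancestry and its
ties carry no boundary information.

**Resolution.** A boundary can only be placed at the discriminating
columns flanking it, whose mean spacing is 1/divergence. At 20% donor
divergence (the cross-genus regime of the motivating comparisons,
~17–18 differences per 90 nt) planted tracts at least twice the window
long are recovered within ±(window − step) = ±40 columns in 98–100% of
replicates; at 10% divergence chance 40-column runs without a
discriminating site blur a few percent of boundaries past that
tolerance, and at 5% the ±40 target is not attainable in general. The
packaged validation therefore runs at 20%.

## Simulators

* **Yule trees**: pure-birth, exponential waits, optional exact rescaling
  of the total branch-length sum (the study-like default is 29 taxa,
  total length 3 — the paper system's depth is not printed, so recovery
  tolerances are always stated relative to generating values).
* **Binary traits**: root from the prior, then exact branch transitions
  via P(t); tip patterns *and* true internal states are returned.
* **Alignments**: Jukes–Cantor only — the recombination and mosaic
  machinery needs divergence, not substitution-model realism.
* **Conversion tracts**: uniform starts, geometric lengths (the minimal
  standard tract-length model) with the mean exposed, clipped and merged;
  the merged list is returned as ground truth.
* **Study fixture**: 29-taxon tree; intron pattern rejection-sampled to
  exactly 22/29 present at μ = 3.51, HEG pattern at μ = 21.88 restricted
  to the intron-present taxa and resampled until dimorphic (cap 10 000).
  Rejection sampling is simple and unbiased enough for a fixture.

What the simulators do **not** emulate: indels (real intron alignments
gap heavily), rate variation across sites and branches, selection on HEG
function, co-conversion of exonic flanks, and phylogenetic uncertainty
(trees are taken as known). Passing tests therefore demonstrate
correctness and calibration of the machinery under its own model — not
that real intron data satisfy that model.

## Problem sizes

Defaults used by the packaged experiments: 200 replicates for rate
recovery and for PHI calibration (200 permutations each), 100 for PHI
power, 50 for breakpoint recovery — sizes at which the Monte-Carlo error
of each reported rate is a few percent, which matches the width of the
bands being checked.

## Known limitations

* Wald intervals from the observed information are approximate for a
  boundary-prone one-parameter model; measured 95% coverage over
  simulated replicates is 0.89–0.97, not exactly 0.95.
* The ER/ARD machinery is strictly two-state; no covarion or
  branch-heterogeneous variants.
* PHI here reports the windowed permutation test (and an optional normal
  approximation to the permutation null); no breakpoint localization is
  attempted — the scanner is descriptive, the test inferential.
* The packaged 29-strain table reproduces the published marginal totals
  and the states of strains fixed by the published text; the remaining
  per-strain assignments are a documented reconstruction (see the file
  header), so analyses of that table illustrate the workflow rather than
  re-derive the published per-strain history.
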