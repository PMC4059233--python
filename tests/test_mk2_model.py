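"""Mk2 likelihood machinery against closed forms and enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from scipy.integrate import quad

from intron_turnover import (
    MkRates,
    ancestral_marginals,
    chi_square_p,
    fit,
    likelihood_ratio,
    likelihood_surface,
    log_likelihood,
    loglik_at_rate,
    parse_newick,
    transition_matrix,
)
from intron_turnover.phylo_io import PhyleticPattern, Phylogeny, TreeNode
from intron_turnover.synthetic_data import simulate_trait, simulate_yule_tree

from conftest import (
    enum_log_likelihood,
    enum_marginals,
    random_pattern,
    random_tree,
)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        P = transition_matrix(MkRates.ard(3.0, 0.5), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_symmetric_stationary_limit(self):
        P = transition_matrix(MkRates.er(1.0), 50.0)
        assert np.allclose(P, 0.5, atol=1e-9)

    @pytest.mark.parametrize("gain,loss,t", [
        (2.0, 1.0, 0.7),
        (0.3, 5.0, 0.05),
        (10.0, 10.0, 2.0),
        (1e-3, 1.0, 3.0),
    ])
    def test_matches_matrix_exponential(self, gain, loss, t):
        Q = np.array([[-gain, gain], [loss, -loss]])
        P = transition_matrix(MkRates.ard(gain, loss), t)
        assert np.abs(P - expm(Q * t)).max() < 1e-10

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            rates = MkRates.ard(*np.exp(rng.uniform(-3, 3, 2)))
            P = transition_matrix(rates, float(rng.uniform(0, 5)))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((P >= 0) & (P <= 1))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        log_gain=st.floats(-2, 2), log_loss=st.floats(-2, 2),
        t1=st.floats(0, 3), t2=st.floats(0, 3),
    )
    def test_chapman_kolmogorov(self, log_gain, log_loss, t1, t2):
        rates = MkRates.ard(math.exp(log_gain), math.exp(log_loss))
        lhs = transition_matrix(rates, t1) @ transition_matrix(rates, t2)
        rhs = transition_matrix(rates, t1 + t2)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(MkRates.er(1.0), -0.1)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            MkRates.ard(0.0, 1.0)
        with pytest.raises(ValueError):
            MkRates.ard(math.inf, 1.0)


class TestLogLikelihood:
    def test_two_leaf_closed_form(self):
        t1, t2, mu = 0.3, 0.8, 1.7
        tree = parse_newick(f"(A:{t1},B:{t2});")
        pattern = PhyleticPattern("c", {"A": 1, "B": 1})
        rates = MkRates.er(mu)
        P1 = transition_matrix(rates, t1)
        P2 = transition_matrix(rates, t2)
        expected = math.log(0.5 * (P1[1, 1] * P2[1, 1] + P1[0, 1] * P2[0, 1]))
        assert log_likelihood(tree, pattern, rates) == pytest.approx(
            expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(3, 7)))
        pattern = random_pattern(rng, tree)
        rates = MkRates.ard(*np.exp(rng.uniform(-2, 2, 2)))
        got = log_likelihood(tree, pattern, rates)
        want = enum_log_likelihood(tree, pattern, rates)
        assert abs(got - want) < 1e-10

    def test_all_present_low_rate_limit(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.1):0.2);")
        pattern = PhyleticPattern("c", {t: 1 for t in "ABCD"})
        assert loglik_at_rate(tree, pattern, 1e-8) == pytest.approx(
            math.log(0.5), abs=1e-6)

    def test_invariant_to_child_order(self):
        rng = np.random.default_rng(11)
        tree = random_tree(rng, 6)
        pattern = random_pattern(rng, tree)
        rates = MkRates.er(2.0)
        before = log_likelihood(tree, pattern, rates)
        for node in tree.postorder():
            node.children.reverse()
        assert log_likelihood(tree, pattern, rates) == pytest.approx(
            before, abs=1e-12)

    def test_invariant_to_branch_subdivision(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        pattern = PhyleticPattern("c", {"A": 1, "B": 0, "C": 1})
        rates = MkRates.ard(1.5, 0.7)
        before = log_likelihood(tree, pattern, rates)
        # split C's branch 0.4 into 0.15 + 0.25 via a degree-2 node
        tree2 = parse_newick("((A:0.1,B:0.2):0.3,(C:0.15):0.25);")
        assert log_likelihood(tree2, pattern, rates) == pytest.approx(
            before, abs=1e-12)

    def test_taxon_mismatch_rejected(self):
        tree = parse_newick("(A:1.0,B:1.0);")
        pattern = PhyleticPattern("c", {"A": 1, "X": 0})
        with pytest.raises(Exception, match="taxa"):
            log_likelihood(tree, pattern, MkRates.er(1.0))


class TestFit:
    def test_monomorphic_boundary(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.1):0.2);")
        pattern = PhyleticPattern("c", {t: 1 for t in "ABCD"})
        res = fit(tree, pattern, model="ER")
        assert res.boundary
        assert res.se["mu"] is None
        assert res.lnl == pytest.approx(math.log(0.5), abs=1e-4)

    def test_fit_consistent_with_loglik_at_rate(self, study_tree):
        sim = simulate_trait(study_tree, MkRates.er(3.5), seed=7)
        res = fit(study_tree, sim.pattern, model="ER")
        assert loglik_at_rate(study_tree, sim.pattern, res.mu) == \
            pytest.approx(res.lnl, abs=1e-9)

    def test_ard_never_below_er(self, study_tree):
        for seed in range(8):
            sim = simulate_trait(study_tree, MkRates.er(3.5), seed=seed)
            er = fit(study_tree, sim.pattern, model="ER")
            ard = fit(study_tree, sim.pattern, model="ARD")
            assert ard.lnl >= er.lnl - 1e-8

    def test_parameter_recovery_quick(self, study_tree):
        """Median ML estimate over 60 simulated patterns lands near the
        generating rate (full-size recovery lives in the acceptance suite)."""
        estimates = []
        for seed in range(60):
            sim = simulate_trait(study_tree, MkRates.er(3.5), seed=seed)
            res = fit(study_tree, sim.pattern, model="ER")
            if not res.boundary:
                estimates.append(res.mu)
        med = float(np.median(estimates))
        assert 0.6 * 3.5 < med < 1.4 * 3.5

    def test_stationary_root_option(self, study_tree):
        sim = simulate_trait(study_tree, MkRates.er(3.5), seed=3)
        res = fit(study_tree, sim.pattern, model="ARD", root="stationary")
        assert res.root_prior == pytest.approx(res.rates.stationary)


class TestLikelihoodRatio:
    def test_identical_fixed_hypotheses(self, study_tree):
        sim = simulate_trait(study_tree, MkRates.er(3.5), seed=5)
        res = likelihood_ratio(study_tree, sim.pattern, 2.0, 2.0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_chi_square_critical_value(self):
        """Upper tail at the df=1, alpha=0.05 critical point, checked
        against direct numeric integration of the chi2_1 density."""
        dens = lambda x: math.exp(-x / 2) / math.sqrt(2 * math.pi * x)
        expected, _ = quad(dens, 3.8415, np.inf)
        assert chi_square_p(3.8415, 1) == pytest.approx(expected, abs=1e-10)
        assert chi_square_p(3.8415, 1) == pytest.approx(0.05, abs=1e-4)

    def test_published_statistics_significance_calls(self):
        # the four printed 2*dlnL values map onto the printed P thresholds
        assert chi_square_p(4.26, 1) < 0.05
        assert chi_square_p(14.68, 1) < 0.001
        assert chi_square_p(4.86, 1) < 0.05
        assert chi_square_p(2.68, 1) > 0.05

    def test_ml_vs_fixed_statistic_nonnegative(self, study_tree):
        sim = simulate_trait(study_tree, MkRates.er(5.0), seed=8)
        res = likelihood_ratio(study_tree, sim.pattern, "ml", 1.0)
        assert res.statistic >= 0.0
        assert 0 < res.p_value <= 1.0


class TestLikelihoodSurface:
    def test_pointwise_equals_loglik_at_rate(self, study_tree):
        sim = simulate_trait(study_tree, MkRates.er(3.5), seed=9)
        grid = np.geomspace(0.1, 100, 25)
        surf = likelihood_surface(study_tree, sim.pattern, grid)
        for mu, lnl in zip(surf.grid, surf.lnl):
            assert lnl == pytest.approx(
                loglik_at_rate(study_tree, sim.pattern, mu), abs=1e-12)

    def test_argmax_at_ml_estimate(self, study_tree):
        sim = simulate_trait(study_tree, MkRates.er(3.5), seed=9)
        res = fit(study_tree, sim.pattern, model="ER")
        grid = np.sort(np.append(np.geomspace(0.1, 100, 30), res.mu))
        surf = likelihood_surface(study_tree, sim.pattern, grid)
        assert surf.mu_at_max == pytest.approx(res.mu)
        assert surf.lnl.max() <= res.lnl + 1e-8

    def test_monomorphic_monotone_decreasing(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.1):0.2);")
        pattern = PhyleticPattern("c", {t: 1 for t in "ABCD"})
        surf = likelihood_surface(tree, pattern, np.geomspace(1e-3, 1e3, 40))
        assert np.all(np.diff(surf.lnl) <= 1e-12)

    def test_bad_grid_rejected(self, study_tree):
        sim = simulate_trait(study_tree, MkRates.er(3.5), seed=9)
        with pytest.raises(ValueError):
            likelihood_surface(study_tree, sim.pattern, [1.0, 0.5])
        with pytest.raises(ValueError):
            likelihood_surface(study_tree, sim.pattern, [-1.0, 0.5])


class TestAncestralMarginals:
    def test_cherry_tiny_branches(self):
        tree = parse_newick("(A:0.000001,B:0.000001);")
        pattern = PhyleticPattern("c", {"A": 1, "B": 1})
        recon = ancestral_marginals(tree, pattern, MkRates.er(1.0))
        (p0, p1), = recon.probs.values()
        assert p1 > 0.999

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_tree(rng, 5)
        pattern = random_pattern(rng, tree)
        rates = MkRates.ard(*np.exp(rng.uniform(-2, 2, 2)))
        recon = ancestral_marginals(tree, pattern, rates)
        want = enum_marginals(tree, pattern, rates)
        for node, (p0, p1) in recon.probs.items():
            assert abs(p0 - want[id(node)][0]) < 1e-10
            assert abs(p1 - want[id(node)][1]) < 1e-10

    def test_saturation_limit(self):
        tree = parse_newick("((A:50,B:50):50,(C:50,D:50):50);")
        pattern = PhyleticPattern("c", {"A": 1, "B": 0, "C": 1, "D": 0})
        recon = ancestral_marginals(tree, pattern, MkRates.er(1.0))
        for p0, p1 in recon.probs.values():
            assert p0 == pytest.approx(0.5, abs=1e-6)

    def test_probabilities_sum_to_one(self, study_tree):
        sim = simulate_trait(study_tree, MkRates.er(3.5), seed=12)
        recon = ancestral_marginals(study_tree, sim.pattern, MkRates.er(3.5))
        assert len(recon.probs) == len(study_tree.internal_nodes())
        for p0, p1 in recon.probs.values():
            assert p0 + p1 == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= p0 <= 1.0
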