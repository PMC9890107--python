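import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from psiseq.frequentist_tests import (
    ProbabilityCI,
    ci_level_for_look,
    ci_verdict,
    collapse_patterns,
    fit_patterns,
    marginal_loglik,
    one_sided_proportion_tests,
    probability_ci,
)
from psiseq.verdicts import Verdict

from conftest import make_table, session_rows


def quad_loglik(patterns, beta0, tau):
    """Oracle marginal log-likelihood via adaptive quadrature per pattern."""
    total = 0.0
    for (k, n), c in patterns.items():
        if tau < 1e-10:
            p = special.expit(beta0)
            li = math.log(math.comb(n, k)) + k * math.log(p) + (n - k) * math.log1p(-p)
        else:

            def f(u):
                p = special.expit(beta0 + u)
                return (
                    p**k
                    * (1 - p) ** (n - k)
                    * math.exp(-0.5 * (u / tau) ** 2)
                    / (tau * math.sqrt(2 * math.pi))
                )

            val, _ = integrate.quad(f, -10 * tau, 10 * tau, limit=200)
            li = math.log(math.comb(n, k)) + math.log(val)
        total += c * li
    return total


class TestCollapsePatterns:
    def test_three_participants(self):
        rows = []
        for pid, k in [("p1", 9), ("p2", 9), ("p3", 10)]:
            rows += session_rows(pid, [i < k for i in range(18)], start_order=len(rows))
        table = make_table(rows)
        assert collapse_patterns(table) == {(9, 18): 2, (10, 18): 1}

    def test_empty(self):
        assert collapse_patterns(make_table([])) == {}


class TestMarginalLikelihood:
    @pytest.mark.parametrize("beta0,tau", [(0.0, 0.3), (0.2, 0.05), (-0.5, 1.2), (0.1, 0.0)])
    def test_matches_quadrature(self, beta0, tau):
        patterns = {(9, 18): 3, (15, 18): 1, (2, 7): 2, (0, 18): 1}
        ours = marginal_loglik(patterns, beta0, tau)
        oracle = quad_loglik(patterns, beta0, tau)
        # 21-node adaptive GH is ~1e-8-accurate even at large tau
        assert ours == pytest.approx(oracle, abs=1e-7)

    def test_collapsed_equals_trial_level(self, rng):
        # the likelihood must be identical whether participants are collapsed
        # into patterns or each kept separate
        ks = rng.binomial(18, 0.55, size=40)
        collapsed: dict = {}
        for k in ks:
            collapsed[(int(k), 18)] = collapsed.get((int(k), 18), 0) + 1
        trial_level = {}  # one "pattern" per participant via unit counts
        total = 0.0
        for k in ks:
            total += marginal_loglik({(int(k), 18): 1}, 0.1, 0.4)
        assert marginal_loglik(collapsed, 0.1, 0.4) == pytest.approx(total, abs=1e-9)

    def test_node_count_stability(self):
        # doubling quadrature nodes moves the loglik by < 1e-8 at a typical fit
        import psiseq.frequentist_tests as ft

        patterns = {(9, 18): 50, (12, 18): 20, (6, 18): 15}
        fit = fit_patterns(patterns)
        base = marginal_loglik(patterns, fit.beta0, max(fit.tau, 0.2))
        saved = (ft._gh_x, ft._gh_w, ft._gh_logw)
        try:
            x, w = np.polynomial.hermite.hermgauss(61)
            ft._gh_x, ft._gh_w, ft._gh_logw = x, w, np.log(w) + x**2
            dense = marginal_loglik(patterns, fit.beta0, max(fit.tau, 0.2))
        finally:
            ft._gh_x, ft._gh_w, ft._gh_logw = saved
        assert base == pytest.approx(dense, abs=1e-8)


class TestFit:
    def test_perfect_balance_boundary(self):
        fit = fit_patterns({(9, 18): 25})
        assert fit.beta0 == pytest.approx(0.0, abs=1e-10)
        assert fit.tau == 0.0
        assert fit.converged

    def test_boundary_ci_equals_single_proportion_wald(self):
        patterns = {(9, 18): 10, (10, 18): 10, (8, 18): 10}
        fit = fit_patterns(patterns)
        k = 9 * 10 + 10 * 10 + 8 * 10
        n = 18 * 30
        phat = k / n
        if fit.tau == 0.0:
            se = 1 / math.sqrt(n * phat * (1 - phat))
            assert fit.se_beta0 == pytest.approx(se, rel=1e-9)
            ci = probability_ci(fit, 0.95)
            z = stats.norm.ppf(0.975)
            lo = special.expit(special.logit(phat) - z * se)
            assert ci.lo == pytest.approx(lo, rel=1e-9)

    def test_two_participant_grid_oracle(self):
        patterns = {(16, 18): 1, (3, 18): 1}  # strong heterogeneity
        fit = fit_patterns(patterns)
        assert fit.converged and fit.tau > 0.1
        # independent grid search on the quadrature-oracle likelihood
        b_grid = np.linspace(-1.0, 1.0, 81)
        t_grid = np.linspace(0.05, 3.0, 60)
        best = max(
            ((quad_loglik(patterns, b, t), b, t) for b in b_grid for t in t_grid),
        )
        # refine around the winner
        b_grid = np.linspace(best[1] - 0.05, best[1] + 0.05, 41)
        t_grid = np.linspace(max(best[2] - 0.1, 1e-3), best[2] + 0.1, 41)
        best = max(
            ((quad_loglik(patterns, b, t), b, t) for b in b_grid for t in t_grid),
        )
        assert fit.loglik == pytest.approx(best[0], abs=1e-4)
        assert fit.beta0 == pytest.approx(best[1], abs=5e-3)
        assert fit.tau == pytest.approx(best[2], abs=1e-2)

    def test_separation_flagged(self):
        fit = fit_patterns({(18, 18): 5})
        assert not fit.converged

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fit_patterns({})


class TestProbabilityCI:
    def test_closed_form(self):
        from psiseq.frequentist_tests import MixedModelFit

        fit = MixedModelFit(0.0, 0.0, 0.1, 0.0, 10, 180, True)
        ci = probability_ci(fit, 0.95)
        assert ci.lo == pytest.approx(special.expit(-0.1 * stats.norm.ppf(0.975)), rel=1e-9)
        assert ci.hi == pytest.approx(0.5488, abs=1e-3)
        assert ci.lo < 0.5 < ci.hi

    def test_degenerate_se(self):
        from psiseq.frequentist_tests import MixedModelFit

        fit = MixedModelFit(0.3, 0.0, 1e-12, 0.0, 10, 180, True)
        ci = probability_ci(fit, 0.99)
        assert ci.lo == pytest.approx(special.expit(0.3), abs=1e-9)
        assert ci.hi == pytest.approx(special.expit(0.3), abs=1e-9)

    def test_unconverged_rejected(self):
        from psiseq.frequentist_tests import MixedModelFit

        fit = MixedModelFit(0.0, 0.0, float("nan"), 0.0, 1, 18, False)
        with pytest.raises(ValueError):
            probability_ci(fit, 0.95)


class TestCIVerdict:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.4911, 0.5067, Verdict.SUPPORT_M0),
            (0.502, 0.520, Verdict.SUPPORT_M1),
            (0.495, 0.515, Verdict.INCONCLUSIVE),
            (0.40, 0.505, Verdict.SUPPORT_M0),  # M0 rule takes precedence
        ],
    )
    def test_rules(self, lo, hi, expected):
        assert ci_verdict(ProbabilityCI(0.9975, lo, hi)) is expected


class TestLookSchedule:
    def test_printed_levels(self):
        assert ci_level_for_look(1) == pytest.approx(0.9975)
        assert ci_level_for_look(2) == pytest.approx(0.99875)
        assert ci_level_for_look(3) == pytest.approx(0.9991667, abs=5e-8)
        assert ci_level_for_look(4) == pytest.approx(0.999375)
        assert ci_level_for_look(5) == pytest.approx(0.9995)

    def test_one_based(self):
        with pytest.raises(ValueError):
            ci_level_for_look(0)


class TestProportionTests:
    def test_low_rate_supports_m0(self):
        res = one_sided_proportion_tests(400, 1000)
        assert res.verdict is Verdict.SUPPORT_M0
        assert res.p_le_sesoi < 1e-10

    def test_high_rate_supports_m1(self):
        res = one_sided_proportion_tests(600, 1000)
        assert res.verdict is Verdict.SUPPORT_M1
        assert res.p_gt_null < 1e-9

    def test_middling_rate_inconclusive(self):
        res = one_sided_proportion_tests(505, 1000)
        assert res.verdict is Verdict.INCONCLUSIVE
        assert res.p_le_sesoi > 0.005 and res.p_gt_null > 0.005

    def test_exact_tails_match_binom(self):
        res = one_sided_proportion_tests(505, 1000)
        assert res.p_le_sesoi == pytest.approx(stats.binom.cdf(505, 1000, 0.51))
        assert res.p_gt_null == pytest.approx(stats.binom.sf(504, 1000, 0.5))

    def test_normal_approximation_variant(self):
        exact = one_sided_proportion_tests(18876, 37836)
        approx = one_sided_proportion_tests(18876, 37836, exact=False)
        assert approx.verdict is exact.verdict
        assert approx.p_le_sesoi == pytest.approx(exact.p_le_sesoi, abs=5e-3)


class TestCoverage:
    def test_null_ci_coverage_near_nominal(self, rng):
        # 0.9 CI from the mixed fit should cover p=0.5 in ~90% of null
        # replicates (homogeneous truth, tau = 0)
        level, reps, n_part = 0.90, 250, 60
        covered = 0
        for _ in range(reps):
            ks = rng.binomial(18, 0.5, size=n_part)
            patterns: dict = {}
            for k in ks:
                patterns[(int(k), 18)] = patterns.get((int(k), 18), 0) + 1
            fit = fit_patterns(patterns)
            ci = probability_ci(fit, level)
            covered += ci.lo <= 0.5 <= ci.hi
        se = math.sqrt(level * (1 - level) / reps)
        assert covered / reps == pytest.approx(level, abs=3.5 * se)
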