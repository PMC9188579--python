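"""Exact binomial CIs, g-test, Kruskal-Wallis: formula oracles and laws."""

import numpy as np
import pytest
import scipy.stats
from statsmodels.stats.proportion import proportion_confint

from morbidmine.stats import (
    DegenerateTableError,
    benjamini_hochberg,
    clopper_pearson,
    g_test,
    kruskal_wallis,
    median_bmi_summary,
)


def binomial_tail_bisect(x, n, level=0.95, tol=1e-12):
    """Independent oracle: invert the exact binomial tails by bisection."""
    alpha = 1 - level

    def upper_tail(p):  # P(X >= x)
        return 1.0 - scipy.stats.binom.cdf(x - 1, n, p)

    def lower_tail(p):  # P(X <= x)
        return scipy.stats.binom.cdf(x, n, p)

    def bisect(f, target, lo, hi, increasing):
        for _ in range(200):
            mid = (lo + hi) / 2
            if (f(mid) > target) == increasing:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else bisect(upper_tail, alpha / 2, 0.0, 1.0, increasing=True)
    upper = 1.0 if x == n else bisect(lower_tail, alpha / 2, 0.0, 1.0, increasing=False)
    return lower, upper


class TestClopperPearson:
    def test_boundary_identities(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 1.0

    @pytest.mark.parametrize(
        "x, n", [(3, 5), (1, 10), (9, 10), (17, 200), (100, 200), (0, 7), (7, 7)]
    )
    def test_matches_tail_inversion_oracle(self, x, n):
        ci = clopper_pearson(x, n, 0.95)
        lo, hi = binomial_tail_bisect(x, n, 0.95)
        assert ci.lower == pytest.approx(lo, abs=1e-8)
        assert ci.upper == pytest.approx(hi, abs=1e-8)

    def test_matches_statsmodels_beta_method(self):
        for x, n in [(3, 5), (42, 500), (0, 20), (20, 20)]:
            lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
            ci = clopper_pearson(x, n, 0.95)
            assert ci.lower == pytest.approx(float(lo) if x else 0.0, abs=1e-10)
            assert ci.upper == pytest.approx(float(hi) if x < n else 1.0, abs=1e-10)

    def test_interval_orders_and_brackets_point(self):
        ci = clopper_pearson(3, 5)
        assert 0 <= ci.lower <= ci.point <= ci.upper <= 1

    def test_width_shrinks_with_n_at_fixed_ratio(self):
        widths = [clopper_pearson(n // 10, n).width for n in (50, 100, 200, 400, 800)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)
        with pytest.raises(ValueError):
            clopper_pearson(1, 10, level=1.0)

    def test_simulated_coverage_is_conservative(self):
        """95% intervals over Bin(200, 0.1) cover p at rate >= 0.95."""
        rng = np.random.default_rng(41)
        n, p, reps = 200, 0.1, 5000
        cis = {x: clopper_pearson(x, n) for x in range(n + 1)}
        draws = rng.binomial(n, p, reps)
        covered = sum(cis[x].lower <= p <= cis[x].upper for x in draws)
        assert covered / reps >= 0.95


class TestGTest:
    def test_zero_on_proportional_table(self):
        res = g_test([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        O = np.array([[10.0, 20.0], [20.0, 10.0]])
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        expected = 2.0 * (O * np.log(O / E)).sum()
        assert g_test(O).statistic == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy_log_likelihood_route(self):
        O = [[30, 70], [45, 55], [25, 75]]
        mine = g_test(O)
        g, p, df, _ = scipy.stats.chi2_contingency(O, correction=False,
                                                   lambda_="log-likelihood")
        assert mine.statistic == pytest.approx(float(g), abs=1e-10)
        assert mine.df == df
        assert mine.p_value == pytest.approx(float(p), abs=1e-12)

    def test_zero_cell_convention(self):
        res = g_test([[0, 10], [10, 10]])  # 0*ln(0) treated as 0
        assert np.isfinite(res.statistic)

    def test_invariances(self):
        O = [[30, 70], [45, 55], [25, 75]]
        base = g_test(O).statistic
        assert g_test(O[::-1]).statistic == pytest.approx(base, abs=1e-12)
        swapped = [[b, a] for a, b in O]
        assert g_test(swapped).statistic == pytest.approx(base, abs=1e-12)

    def test_degenerate_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            g_test([[0, 0], [5, 5]])
        with pytest.raises(DegenerateTableError):
            g_test([[0, 5], [0, 5]])

    def test_agrees_with_pearson_chi2_for_large_null_counts(self):
        """Asymptotic equivalence near independence: with all expected
        counts large and a common row distribution, G tracks Pearson."""
        rng = np.random.default_rng(43)
        for _ in range(20):
            n = 2000
            x = rng.binomial(n, 0.3, size=4)
            O = np.stack([x, n - x], axis=1).astype(float)
            g = g_test(O).statistic
            chi2 = scipy.stats.chi2_contingency(O, correction=False)[0]
            if chi2 > 1e-2:
                assert abs(g - chi2) / chi2 < 0.05

    def test_williams_correction_shrinks_statistic(self):
        O = [[8, 3], [2, 9]]
        assert g_test(O, williams=True).statistic < g_test(O).statistic

    def test_null_rejection_rate(self):
        """Six races at common prevalence 0.2: rejection at 0.05 stays nominal."""
        rng = np.random.default_rng(44)
        reps, groups, n, p = 2000, 6, 500, 0.2
        rejections = 0
        for _ in range(reps):
            x = rng.binomial(n, p, groups)
            table = np.stack([x, n - x], axis=1)
            if (table.sum(0) == 0).any():
                continue
            if g_test(table).p_value < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) <= 0.02


class TestKruskalWallis:
    def test_zero_for_identical_multisets(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_rank_formula(self):
        # groups [1,2,3] and [4,5,6]: ranks 1..6, no ties
        g1, g2 = [1, 2, 3], [4, 5, 6]
        N = 6
        r1, r2 = 1 + 2 + 3, 4 + 5 + 6
        expected = 12 / (N * (N + 1)) * (r1**2 / 3 + r2**2 / 3) - 3 * (N + 1)
        assert kruskal_wallis([g1, g2]).statistic == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(45)
        for _ in range(20):
            groups = [rng.integers(0, 6, rng.integers(5, 20)) for _ in range(3)]
            mine = kruskal_wallis(groups)
            ref = scipy.stats.kruskal(*groups)
            assert mine.statistic == pytest.approx(float(ref.statistic), abs=1e-10)
            assert mine.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(46)
        groups = [rng.normal(size=12) for _ in range(4)]
        base = kruskal_wallis(groups).statistic
        transformed = [np.exp(g) for g in groups]
        assert kruskal_wallis(transformed).statistic == pytest.approx(base, abs=1e-10)

    def test_all_identical_values_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(47)
        reps, groups, n = 2000, 6, 50
        rejections = 0
        for _ in range(reps):
            data = [rng.normal(size=n) for _ in range(groups)]
            if kruskal_wallis(data).p_value < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) <= 0.02


class TestMedians:
    def test_median_bmi_summary(self, small_result):
        summary = median_bmi_summary(small_result.cohort)
        with_ob = summary[summary["obesity_class"] == "with_obesity"]
        without = summary[summary["obesity_class"] == "without_obesity"]
        assert (with_ob["median_bmi"] >= 30).all()
        assert (without["median_bmi"] < 30).all()
        # generator targets ~34 / ~25.5
        assert with_ob["median_bmi"].between(32, 36).all()
        assert without["median_bmi"].between(24, 27).all()

    def test_even_count_median_rule(self):
        import pandas as pd

        cohort = pd.DataFrame(
            {
                "included": [True, True],
                "age_band": ["elderly"] * 2,
                "obesity_class": ["without_obesity"] * 2,
                "race": ["Caucasian"] * 2,
                "mean_bmi": [24.0, 26.0],
            }
        )
        out = median_bmi_summary(cohort)
        assert out["median_bmi"].iloc[0] == 25.0


def test_benjamini_hochberg_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.5, 0.8]
    adj = benjamini_hochberg(p)
    assert (adj >= np.array(p) - 1e-15).all()
    assert (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()
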