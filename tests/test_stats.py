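"""Statistical layer: correlations, group tests, TOST, quality gating."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from deepseep import synthetic_data as syn
from deepseep.stats import (
    depth_trend,
    detectable_effect,
    group_tests,
    pearson,
    power_welch_two_sided,
    quality_gate,
    tost_equivalence,
)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_hand_computed_covariance_ratio(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([0.5, 3.0, 2.0, 8.0, 9.5])
        xc, yc = x - x.mean(), y - y.mean()
        manual = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        r, _ = pearson(x, y)
        assert r == pytest.approx(manual)

    def test_null_pvalues_uniform(self):
        """Under independence the p-value distribution is uniform (KS check
        over 500 seeded simulations)."""
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(500):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            ps.append(pearson(x, y)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


def truth_frame(**kwargs):
    panels = syn.generate_site_panel(**kwargs)
    df = syn.panel_truth(panels).rename(columns={"true_ptr": "value"})
    return df


class TestDepthTrend:
    def test_noise_free_negative_slope_gives_minus_one(self):
        df = truth_frame(seed=5, irep_slope=-1e-4, irep_noise_sd=0.0, n_high_co2=0)
        for scope in ("per_value", "per_ecosystem_median"):
            res = depth_trend(df, scope=scope)
            assert res.r == pytest.approx(-1.0, abs=1e-9)
            assert res.p < 1e-6

    def test_excluding_offset_sites_strengthens_trend(self):
        """Panels built with elevated-offset (CO2-impacted) sites: masking
        them out makes the negative correlation stronger."""
        df = truth_frame(seed=5, irep_slope=-1.3e-4, irep_noise_sd=0.02,
                         n_high_co2=3, high_co2_offset=0.4)
        r_all = depth_trend(df).r
        r_masked = depth_trend(df, exclude=df.high_co2.to_numpy()).r
        assert r_masked < r_all < 0

    def test_null_slope_r_centered_on_zero(self):
        rs = [depth_trend(truth_frame(seed=s, irep_slope=0.0, irep_noise_sd=0.1,
                                      n_high_co2=0)).r
              for s in range(30)]
        assert abs(np.mean(rs)) < 0.12

    def test_median_scope_needs_three_sites(self):
        df = truth_frame(seed=1, n_sites=3).query("site_id != 'site03'")
        with pytest.raises(ValueError, match="3 sites"):
            depth_trend(df, scope="per_ecosystem_median")


class TestGroupTests:
    def test_identical_groups_uninformative(self):
        a = np.arange(10.0)
        for kind in ("welch_t", "mann_whitney_u"):
            _, p = group_tests(a, a.copy(), kind=kind)
            assert p > 0.95

    def test_huge_effect_tiny_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 30)
        b = rng.normal(10, 1, 30)
        _, p = group_tests(a, b, kind="welch_t")
        assert p < 1e-8

    def test_kruskal_on_two_groups_matches_mann_whitney(self):
        """For two tie-free groups the Kruskal-Wallis chi-square equals the
        squared (non-continuity) normal approximation of U."""
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 15)
        _, p_kw = group_tests(a, b, kind="kruskal_wallis")
        p_mw = sps.mannwhitneyu(a, b, alternative="two-sided",
                                use_continuity=False, method="asymptotic").pvalue
        assert p_kw == pytest.approx(p_mw, abs=1e-10)

    def test_kruskal_three_groups(self):
        rng = np.random.default_rng(5)
        stat, p = group_tests(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                              "kruskal_wallis", rng.normal(3, 1, 10))
        assert p < 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            group_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="anova")


class TestTost:
    def test_bound_matches_brute_force_power_grid(self):
        """Bisection bound vs an independent grid search over the power curve
        of statsmodels' two-sample t-test power."""
        from statsmodels.stats.power import TTestIndPower
        n_a, n_b = 14, 18
        d_star = detectable_effect(n_a, n_b, power=0.33)
        grid = np.linspace(1e-4, 3.0, 30001)
        pw = TTestIndPower().power(effect_size=grid, nobs1=n_a,
                                   ratio=n_b / n_a, alpha=0.05,
                                   alternative="two-sided")
        oracle = grid[np.nanargmin(np.abs(np.asarray(pw) - 0.33))]
        assert d_star == pytest.approx(oracle, abs=1e-4)

    def test_power_function_sane(self):
        assert power_welch_two_sided(0.0, 20, 20) == pytest.approx(0.05, abs=1e-6)
        assert power_welch_two_sided(2.0, 20, 20) > 0.99

    def test_identical_groups_equivalent_with_pilot_bound(self):
        """Zero observed effect is declared equivalent when the bound derives
        from a smaller reference design than the tested one."""
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 200)
        res = tost_equivalence(a, a.copy(), bound_n_a=10, bound_n_b=10)
        assert res.verdict == "equivalent"
        assert res.lower == -res.upper

    def test_same_design_bound_cannot_declare_equivalence(self):
        """With the bound derived from the tested groups themselves, the
        33%-power noncentrality sits below the one-sided critical value, so
        even a zero observed difference stays 'not shown'."""
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 200)
        res = tost_equivalence(a, a.copy())
        assert res.verdict == "not shown"

    def test_large_effect_not_shown(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 30)
        b = rng.normal(3, 1, 30)
        res = tost_equivalence(a, b, bound_n_a=10, bound_n_b=10)
        assert res.verdict == "not shown"

    def test_bound_monotone_decreasing_in_n(self):
        bounds = [detectable_effect(n, n, power=0.33) for n in (5, 10, 20, 50, 100)]
        assert all(b2 < b1 for b1, b2 in zip(bounds, bounds[1:]))

    def test_unreachable_power_rejected(self):
        with pytest.raises(ValueError, match="power"):
            detectable_effect(10, 10, power=0.04)


class TestQualityGate:
    def test_inclusive_boundaries_retained(self):
        table = pd.DataFrame({"genome": ["a"], "completeness": [70.0],
                              "contamination": [10.0]})
        assert len(quality_gate(table)) == 1

    def test_below_completeness_dropped(self):
        table = pd.DataFrame({"completeness": [69.9], "contamination": [5.0]})
        assert quality_gate(table).empty

    def test_matches_brute_force_filter(self, rng):
        table = pd.DataFrame({
            "completeness": rng.uniform(0, 100, 200),
            "contamination": rng.uniform(0, 100, 200),
        })
        got = quality_gate(table)
        expected = [i for i in table.index
                    if table.completeness[i] >= 70 and table.contamination[i] <= 10]
        assert list(got.index) == expected

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="contamination"):
            quality_gate(pd.DataFrame({"completeness": [80.0]}))
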