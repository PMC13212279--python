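import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from standthin.growth import (
    ba_change_series,
    bal,
    basal_area,
    dbh_from_basal_area,
    growth_intervals,
    plot_ba_series,
    pressler_rate,
    recovery_fit,
    stand_summary,
    subplot_ba_table,
)
from standthin.inventory import TreeHistory, link_censuses

from conftest import make_inventory


class TestBasalArea:
    def test_hand_values(self):
        assert basal_area(2.0) == pytest.approx(np.pi)
        assert basal_area(10.0) == pytest.approx(78.5398, abs=1e-4)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            basal_area(0.0)

    def test_inverse(self):
        d = np.array([5.0, 17.3, 60.0])
        np.testing.assert_allclose(dbh_from_basal_area(basal_area(d)), d)


class TestPresslerRate:
    def test_no_change_is_zero(self):
        assert pressler_rate(100.0, 100.0, 5) == 0.0

    def test_hand_case(self):
        # (150-100)/(150+100) * 200/5 = 0.2 * 40
        assert pressler_rate(100.0, 150.0, 5) == pytest.approx(8.0)

    @pytest.mark.parametrize("n", [1, 2, 11])
    def test_doubling_closed_form(self, n):
        assert pressler_rate(50.0, 100.0, n) == pytest.approx(200.0 / (3 * n))

    @settings(deadline=None, max_examples=50)
    @given(
        a=hst.floats(1, 1e4), b=hst.floats(1, 1e4),
        n=hst.integers(1, 20),
    )
    def test_antisymmetry(self, a, b, n):
        assert pressler_rate(a, b, n) == pytest.approx(-pressler_rate(b, a, n), abs=1e-9)


class TestBal:
    def toy(self):
        return make_inventory([
            ("a", "SP01", 0, 0, 1, 1, 10.0),
            ("b", "SP01", 0, 0, 2, 2, 20.0),
            ("c", "SP01", 0, 0, 3, 3, 30.0),
        ])

    def test_largest_tree_has_zero(self):
        out = bal(self.toy().trees)
        assert out.iloc[2] == 0.0

    def test_middle_tree_sums_larger_only(self):
        out = bal(self.toy().trees)
        assert out.iloc[1] == pytest.approx(np.pi * 15**2)  # 706.858

    def test_smallest_tree_sums_all_others(self):
        out = bal(self.toy().trees)
        assert out.iloc[0] == pytest.approx(basal_area(20.0) + basal_area(30.0))

    def test_subplot_scope_ignores_other_subplots(self):
        inv = make_inventory([
            ("a", "SP01", 0, 0, 1, 1, 10.0),
            ("b", "SP01", 1, 1, 2, 2, 50.0),
        ])
        assert bal(inv.trees, scope="subplot").iloc[0] == 0.0
        assert bal(inv.trees, scope="plot").iloc[0] == pytest.approx(basal_area(50.0))

    def test_equal_dbh_trees_share_bal(self):
        inv = make_inventory([
            ("a", "SP01", 0, 0, 1, 1, 20.0),
            ("b", "SP01", 0, 0, 2, 2, 20.0),
            ("c", "SP01", 0, 0, 3, 3, 30.0),
        ])
        out = bal(inv.trees)
        assert out.iloc[0] == out.iloc[1] == pytest.approx(basal_area(30.0))

    def test_non_increasing_in_subject_dbh(self):
        rng = np.random.default_rng(0)
        inv = make_inventory([
            (f"t{i}", "SP01", 0, 0, i % 20, i // 20, d)
            for i, d in enumerate(rng.uniform(5, 60, 50))
        ])
        out = bal(inv.trees)
        df = pd.DataFrame({"dbh": inv.trees["dbh"], "bal": out}).sort_values("dbh")
        assert (np.diff(df["bal"]) <= 1e-9).all()


class TestStandSummary:
    def test_uniform_four_trees(self):
        inv = make_inventory([(f"t{i}", "SP01", 0, 0, i, i, 10.0) for i in range(4)])
        s = stand_summary(inv.trees, 0)
        assert s.dg == 10.0 and s.ddom == 10.0 and s.n_per_ha == 100.0

    def test_quadratic_mean_hand_case(self):
        inv = make_inventory([("a", "SP01", 0, 0, 1, 1, 6.0), ("b", "SP01", 0, 0, 2, 2, 8.0)])
        s = stand_summary(inv.trees, 0)
        assert s.dg == pytest.approx(np.sqrt(50.0))
        assert s.ddom_flagged  # fewer than 4 trees

    def test_density_scaling(self):
        inv = make_inventory([(f"t{i}", "SP01", 0, 0, i % 20, i // 20, 10.0) for i in range(20)])
        assert stand_summary(inv.trees, 0).n_per_ha == 500.0

    def test_ddom_is_mean_of_four_largest(self):
        dbhs = [5, 10, 15, 20, 25, 30]
        inv = make_inventory([(f"t{i}", "SP01", 0, 0, i, i, d) for i, d in enumerate(dbhs)])
        assert stand_summary(inv.trees, 0).ddom == pytest.approx(np.mean([30, 25, 20, 15]))

    @settings(deadline=None, max_examples=50)
    @given(d=hst.lists(hst.floats(5, 100), min_size=1, max_size=30))
    def test_dg_dominates_arithmetic_mean(self, d):
        inv = make_inventory([(f"t{i}", "SP01", 0, 0, 1, 1, x) for i, x in enumerate(d)])
        s = stand_summary(inv.trees, 0)
        assert s.dg >= np.mean(d) - 1e-9
        if len(d) == 1:
            assert s.dg == pytest.approx(d[0])  # equality iff all equal


class TestGrowthIntervals:
    def test_bai_and_rate_from_history(self):
        h = TreeHistory("a", "SP01", years=[0, 2], dbh=[10.0, 12.0])
        [iv] = growth_intervals({"a": h})
        assert iv.bai == pytest.approx((basal_area(12.0) - basal_area(10.0)) / 2)
        assert iv.ba_rate == pytest.approx(
            pressler_rate(basal_area(10.0), basal_area(12.0), 2))


def census_pair(scale0, scale1, years=(0, 11)):
    """Two censuses of a 2x2-subplot plot with per-subplot DBH scaling."""
    invs = []
    for year, scale in zip(years, (scale0, scale1)):
        recs = []
        for r in range(2):
            for c in range(2):
                for i in range(5):
                    recs.append((f"t{r}{c}{i}", "SP01", r, c, i + 1, i + 1,
                                 10.0 * scale[(r, c)]))
        invs.append(make_inventory(recs, census_year=year))
    return invs


class TestBaChangeSeries:
    def test_static_stand_rate_zero(self):
        scale = {(r, c): 1.0 for r in range(2) for c in range(2)}
        out = ba_change_series(census_pair(scale, scale))
        assert out["mean"].iloc[0] == 0.0 and out["sd"].iloc[0] == 0.0

    def test_uniform_doubling_of_ba_closed_form(self):
        # BA doubles when DBH scales by sqrt(2); Pressler gives 200/(3*11)
        s0 = {(r, c): 1.0 for r in range(2) for c in range(2)}
        s1 = {k: np.sqrt(2.0) for k in s0}
        out = ba_change_series(census_pair(s0, s1))
        assert out["mean"].iloc[0] == pytest.approx(200.0 / 33, abs=1e-9)
        assert out["sd"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_mean_sd_match_direct_oracle(self):
        rng = np.random.default_rng(1)
        s0 = {(r, c): 1.0 for r in range(2) for c in range(2)}
        s1 = {k: rng.uniform(1.05, 1.4) for k in s0}
        out = ba_change_series(census_pair(s0, s1))
        rates = [pressler_rate(1.0, s1[k] ** 2, 11) for k in s0]  # BA scales as dbh^2
        assert out["mean"].iloc[0] == pytest.approx(np.mean(rates))
        assert out["sd"].iloc[0] == pytest.approx(np.std(rates, ddof=1))

    def test_compound_rate_variant(self):
        s0 = {(r, c): 1.0 for r in range(2) for c in range(2)}
        s1 = {k: np.sqrt(2.0) for k in s0}
        out = ba_change_series(census_pair(s0, s1), method="compound")
        assert out["mean"].iloc[0] == pytest.approx((2 ** (1 / 11) - 1) * 100)

    def test_recruit_exclusion_mode(self):
        invs = census_pair({(r, c): 1.0 for r in range(2) for c in range(2)},
                           {(r, c): 1.0 for r in range(2) for c in range(2)})
        extra = invs[1].trees.iloc[[0]].assign(tree_id="recruit", dbh=6.0)
        invs[1].trees = pd.concat([invs[1].trees, extra], ignore_index=True)
        with_r = ba_change_series(invs, include_recruits=True)
        without = ba_change_series(invs, include_recruits=False)
        assert with_r["mean"].iloc[0] > 0.0
        assert without["mean"].iloc[0] == 0.0


class TestRecoveryFit:
    def line_series(self, intercept, slope, years=(0, 2, 4, 7, 11)):
        y = np.asarray(years, dtype=float)
        return y, intercept + slope * y

    def test_parallel_below_control_not_reached(self):
        yrs, ctrl = self.line_series(30.0, 0.5)
        cfit = recovery_fit(yrs, ctrl, "ctrl")
        _, ba = self.line_series(20.0, 0.5)
        fit = recovery_fit(yrs, ba, "low", control_fit=cfit, thinning_year=0)
        assert fit.control_crossing_year is None

    def test_line_intersection_hand_case(self):
        yrs, ctrl = self.line_series(30.0, 0.5)
        cfit = recovery_fit(yrs, ctrl, "ctrl")
        _, ba = self.line_series(20.0, 1.0)  # 10 below, closing at 0.5/yr -> 20 yr
        fit = recovery_fit(yrs, ba, "low", control_fit=cfit, thinning_year=0)
        assert fit.years_to_control == pytest.approx(20.0)

    def test_baseline_crossing(self):
        yrs, ba = self.line_series(24.0, 0.75)  # hits 30 at year 8
        fit = recovery_fit(yrs, ba, "low", baseline=30.0, thinning_year=0)
        assert fit.years_to_baseline == pytest.approx(8.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_declining_stand_never_crosses(self):
        yrs, ba = self.line_series(25.0, -0.2)
        fit = recovery_fit(yrs, ba, "x", baseline=30.0, thinning_year=0)
        assert fit.baseline_crossing_year is None

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            recovery_fit([0, 2], [10, 11], "x")


class TestAggregationConsistency:
    def test_plot_ba_equals_mean_of_subplot_ba(self, csr_stand):
        tab = subplot_ba_table([csr_stand])
        plot = plot_ba_series([csr_stand])
        year0 = tab[tab.year == 0]
        assert plot["ba_m2_ha"].iloc[0] == pytest.approx(year0["ba_m2_ha"].mean())
        # per-ha scaling: 0.04-ha subplot values are x25 the raw m2 sums
        raw_m2 = basal_area(csr_stand.trees["dbh"].to_numpy()).sum() / 1e4
        assert year0["ba_m2_ha"].sum() * 0.04 == pytest.approx(raw_m2)
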