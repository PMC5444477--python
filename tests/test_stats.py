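"""Tests of the growth statistics: ratio of means, intervals, tests.

Frozen expected values were computed by an independent script evaluating
the textbook formulas directly (pooled t, hand sums-of-squares ANOVA,
log-scale ratio interval) before this implementation existed.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import anisocell as ac


class TestBonferroniLevel:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.05, 7, 1 - 0.05 / 7), (0.05, 1, 0.95), (0.01, 2, 0.995)],
    )
    def test_values(self, alpha, m, expected):
        assert ac.bonferroni_level(alpha, m) == pytest.approx(expected)

    def test_seven_comparisons_rounds_to_99_3_percent(self):
        assert round(100 * ac.bonferroni_level(0.05, 7), 1) == 99.3

    @given(st.integers(min_value=1, max_value=100))
    def test_strictly_increasing_in_m(self, m):
        assert ac.bonferroni_level(0.05, m + 1) > ac.bonferroni_level(0.05, m)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ac.bonferroni_level(0.05, 0)
        with pytest.raises(ValueError):
            ac.bonferroni_level(1.5, 7)


class TestBootstrapCI:
    def test_constant_data_degenerate(self):
        lo, hi = ac.bootstrap_ci(np.full(20, 4.2), seed=0)
        assert lo == pytest.approx(4.2, rel=1e-14)
        assert hi == pytest.approx(4.2, rel=1e-14)
        assert hi - lo <= 1e-12

    def test_deterministic_under_seed(self, rng):
        v = rng.normal(size=50)
        assert ac.bootstrap_ci(v, seed=9) == ac.bootstrap_ci(v, seed=9)
        assert ac.bootstrap_ci(v, seed=9) != ac.bootstrap_ci(v, seed=10)

    def test_agrees_with_classical_t_interval(self, rng):
        v = rng.normal(size=1000)
        lo, hi = ac.bootstrap_ci(v, np.mean, n_iter=1000, level=0.95, seed=1)
        t_half = sps.t.ppf(0.975, 999) * v.std(ddof=1) / np.sqrt(1000)
        width_ratio = (hi - lo) / (2 * t_half)
        assert abs(width_ratio - 1.0) < 0.10

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            ac.bootstrap_ci([1.0], seed=0)
        with pytest.raises(ValueError):
            ac.bootstrap_ci([1.0, 2.0], n_iter=0, seed=0)


class TestRatioOfMeans:
    def test_equal_means_give_one(self):
        assert ac.ratio_of_means([2, 4], [3, 3]) == pytest.approx(1.0)

    def test_simple_ratio(self):
        assert ac.ratio_of_means([2, 4], [1, 1]) == pytest.approx(3.0)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=30),
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=30),
    )
    def test_log_identity(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        r = ac.ratio_of_means(x, y)
        assert r == pytest.approx(x.mean() / y.mean(), rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            ac.ratio_of_means([1.0, -2.0], [1.0, 1.0])


class TestRatioInterval:
    def test_frozen_oracle(self):
        # independent evaluation of the printed formulas: x={1,2,4}, y={1,1,2}
        rr = ac.ratio_interval([1.0, 2.0, 4.0], [1.0, 1.0, 2.0], level=0.95)
        assert rr.ratio == pytest.approx(1.75)
        assert rr.df == 4
        assert rr.interval_halfwidth == pytest.approx(1.2829900644315408)
        assert rr.ci_low == pytest.approx(0.48511258716692524)
        assert rr.ci_high == pytest.approx(6.312967506955673)

    def test_constant_groups_degenerate(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rr = ac.ratio_interval([2.0, 2.0], [1.0, 1.0])
        assert rr.ci_low == rr.ci_high == rr.ratio == pytest.approx(2.0)

    def test_identical_samples_symmetric_on_log_scale(self, rng):
        x = rng.lognormal(0, 0.3, size=40)
        rr = ac.ratio_interval(x, x, level=0.95)
        assert rr.ratio == pytest.approx(1.0)
        assert np.log(rr.ci_high) == pytest.approx(-np.log(rr.ci_low))

    def test_halfwidth_decreases_with_n_and_vanishes(self):
        # hold sample moments fixed by replicating the same values
        base_x, base_y = np.array([1.0, 2.0, 4.0]), np.array([1.0, 1.0, 2.0])
        widths = []
        for reps in (1, 4, 16, 64):
            rr = ac.ratio_interval(np.tile(base_x, reps), np.tile(base_y, reps))
            widths.append(rr.interval_halfwidth)
        assert all(a > b for a, b in zip(widths, widths[1:]))
        assert widths[-1] < 0.2 * widths[0]

    def test_ci_brackets_ratio(self, rng):
        x = rng.lognormal(0.3, 0.4, size=25)
        y = rng.lognormal(0.0, 0.4, size=30)
        rr = ac.ratio_interval(x, y)
        assert rr.ci_low <= rr.ratio <= rr.ci_high
        assert rr.ci_low > 0

    def test_coverage_of_true_ratio(self, rng):
        """95% CI covers the true ratio of means in 92-98% of replicates
        (lognormal groups, true ratio 1.4, n = 100/group, sigma 0.2)."""
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            x = rng.lognormal(np.log(1.4), 0.2, size=100)
            y = rng.lognormal(0.0, 0.2, size=100)
            rr = ac.ratio_interval(x, y, level=0.95)
            if rr.ci_low <= 1.4 <= rr.ci_high:
                hits += 1
        assert 0.92 <= hits / n_rep <= 0.98


class TestTTest:
    def test_frozen_oracle(self):
        res = ac.t_test([3.1, 2.9, 3.4, 3.0], [2.5, 2.8, 2.6])
        assert res.statistic == pytest.approx(3.1622776601683813)
        assert res.pvalue == pytest.approx(0.025031015818452882)
        assert res.df == (5,)

    def test_identical_samples(self):
        res = ac.t_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_antisymmetry(self, rng):
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
        a, b = ac.t_test(x, y), ac.t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_type_one_error_calibrated(self, rng):
        """Rejection rate at alpha 0.05 within [0.03, 0.07] under the null."""
        rejections = sum(
            ac.t_test(rng.normal(size=20), rng.normal(size=20)).pvalue < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rejections / 2000 <= 0.07


class TestAnovaInteraction:
    @staticmethod
    def _table(c00, c01, c10, c11):
        rows = []
        for vals, t, p in [(c00, 4, "H1"), (c01, 4, "H2"), (c10, 18, "H1"), (c11, 18, "H2")]:
            rows += [{"time_hai": t, "position": p, "resp": v} for v in vals]
        return pd.DataFrame(rows)

    def test_additive_data_zero_interaction(self):
        # response = a_time + b_position exactly -> interaction SS = 0
        tab = self._table([1, 1], [2, 2], [3, 3], [4, 4])
        res = ac.anova_interaction(tab, "resp", log_scale=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_frozen_hand_computed_oracle(self):
        tab = self._table([1, 2, 3], [2, 3, 4], [5, 6, 7], [3, 4, 5])
        res = ac.anova_interaction(tab, "resp", log_scale=False)
        assert res.statistic == pytest.approx(6.75)
        assert res.pvalue == pytest.approx(0.0317124874100193)
        assert res.df == (1, 8)

    def test_order_invariance(self, rng):
        tab = self._table(rng.normal(size=5) + 5, rng.normal(size=5) + 5,
                          rng.normal(size=5) + 6, rng.normal(size=5) + 7)
        shuffled = tab.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = ac.anova_interaction(tab, "resp", log_scale=False)
        b = ac.anova_interaction(shuffled, "resp", log_scale=False)
        assert a.statistic == pytest.approx(b.statistic)

    def test_empty_design_cell_named(self):
        tab = self._table([1, 2], [2, 3], [3, 4], [4, 5])
        tab = tab[~((tab["time_hai"] == 18) & (tab["position"] == "H2"))]
        with pytest.raises(ValueError, match="empty design cell"):
            ac.anova_interaction(tab, "resp", log_scale=False)

    def test_type_one_error_under_null(self, rng):
        """No-interaction null: rejection rate at alpha 0.05 in [0.03, 0.07]."""
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            tab = self._table(rng.normal(size=8), rng.normal(size=8) + 1,
                              rng.normal(size=8) + 2, rng.normal(size=8) + 3)
            if ac.anova_interaction(tab, "resp", log_scale=False).pvalue < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


def make_records(layer_ratios, sigma=0.1, n=200, seed=0, base=100.0):
    """Two per-cell tables (t0, t1) with known per-(layer, position) volume
    ratios; lognormal cell-to-cell variation."""
    rng = np.random.default_rng(seed)
    rows0, rows1 = [], []
    cid = 1
    for (layer, pos), ratio in layer_ratios.items():
        v0 = base * rng.lognormal(0.0, sigma, size=n)
        v1 = base * ratio * rng.lognormal(0.0, sigma, size=n)
        for v in v0:
            rows0.append({"cell_id": cid, "replicate_id": 1 + cid % 4, "time_hai": 4.0,
                          "position": pos, "layer": layer, "volume_um3": v,
                          "len_long_um": v ** (1 / 3), "len_rad_um": v ** (1 / 3),
                          "len_circ_um": v ** (1 / 3), "radial_dist_um": 10.0 * layer,
                          "axis_t": 0.25 if pos == "H1" else 0.75})
            cid += 1
        for v in v1:
            rows1.append({"cell_id": cid, "replicate_id": 1 + cid % 4, "time_hai": 18.0,
                          "position": pos, "layer": layer, "volume_um3": v,
                          "len_long_um": v ** (1 / 3), "len_rad_um": v ** (1 / 3),
                          "len_circ_um": v ** (1 / 3), "radial_dist_um": 10.0 * layer,
                          "axis_t": 0.25 if pos == "H1" else 0.75})
            cid += 1
    return pd.DataFrame(rows0), pd.DataFrame(rows1)


class TestLayerGrowthModel:
    def test_identical_tables_all_ratios_one_no_flags(self):
        t0, _ = make_records({(1, "H1"): 1.0, (1, "H2"): 1.0}, seed=5)
        res = ac.compare_layers(t0, t0, metrics=("volume_um3",))
        assert np.allclose(res.table["ratio"], 1.0)
        assert not res.table["t_sig"].any()
        assert not res.table["anova_sig"].any()

    def test_true_ratios_recovered_within_ci(self):
        truth = {(l, p): r for l, r in zip(range(1, 8),
                                           [1.1, 1.2, 1.4, 1.8, 1.5, 1.3, 1.15])
                 for p in ("H1", "H2")}
        t0, t1 = make_records(truth, sigma=0.1, n=200, seed=11)
        res = ac.compare_layers(t0, t1, metrics=("volume_um3",))
        for _, row in res.table.iterrows():
            true_r = truth[(row["layer"], row["position"])]
            assert abs(row["ratio"] / true_r - 1.0) < 0.05
            assert row["ci_low"] <= true_r <= row["ci_high"]

    def test_interaction_flagged_for_position_dependent_growth(self):
        truth = {(1, "H1"): 1.5, (1, "H2"): 1.1}
        t0, t1 = make_records(truth, sigma=0.1, n=200, seed=21)
        res = ac.compare_layers(t0, t1, metrics=("volume_um3",), m=7)
        assert res.table["anova_sig"].all()

    def test_seven_layers_give_corrected_level(self):
        truth = {(l, p): 1.2 for l in range(1, 8) for p in ("H1", "H2")}
        t0, t1 = make_records(truth, sigma=0.1, n=30, seed=2)
        model = ac.LayerGrowthModel(t0, t1, metrics=("volume_um3",))
        assert model.m == 7
        assert model.corrected_level == pytest.approx(1 - 0.05 / 7)
        res = model.fit()
        per_position = res.table.groupby("position").size()
        assert (per_position == 7).all()

    def test_one_sided_layer_excluded_with_warning(self):
        t0, t1 = make_records({(1, "H1"): 1.2, (1, "H2"): 1.2,
                               (2, "H1"): 1.2, (2, "H2"): 1.2}, n=20, seed=3)
        t1 = t1[t1["layer"] != 2]
        with pytest.warns(UserWarning, match="excluded"):
            model = ac.LayerGrowthModel(t0, t1, metrics=("volume_um3",))
        assert model.layers == [1]

    def test_summary_mentions_corrected_level(self):
        t0, t1 = make_records({(1, "H1"): 1.2, (1, "H2"): 1.2}, n=20, seed=4)
        res = ac.compare_layers(t0, t1, metrics=("volume_um3",), m=7)
        assert "99.3%" in res.summary()
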