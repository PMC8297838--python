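import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tagmove import (
    adjust_by,
    body_mass_tests,
    compare_to_control,
    mann_whitney_u,
    medians_table,
    normality_check,
    percent_change,
    slope_analysis,
)

from conftest import synthetic_properties_table


def enumeration_mann_whitney(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_of(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y) + 0.5 * sum(
            1 for x in sample_a for y in sample_b if x == y
        )

    u_obs = u_of(a, b)
    mean_u = n_a * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = set(idx)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        u = u_of(ga, gb)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def hand_by_stepup(p):
    """Direct transcription of the Benjamini-Yekutieli step-up formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * c_m * p[i] / rank))
        adj[i] = running
    return adj


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_symmetry_and_u_complement(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=9)
        u_ab, p_ab = mann_whitney_u(a, b)
        u_ba, p_ba = mann_whitney_u(b, a)
        assert p_ab == pytest.approx(p_ba)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            _, p = mann_whitney_u(rng.normal(size=15), rng.normal(size=15))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestAdjustBY:
    def test_hand_computed_example(self):
        adj = adjust_by([0.01, 0.02, 0.9])
        assert adj == pytest.approx([0.055, 0.055, 1.0])

    def test_single_p_identity(self):
        assert adjust_by([0.03]) == pytest.approx([0.03])

    def test_dominates_raw_and_preserves_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        adj = adjust_by(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        assert adjust_by(p)[perm] == pytest.approx(adjust_by(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_by([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=25,
        )
    )
    def test_stepup_properties_hold_for_arbitrary_inputs(self, p):
        adj = adjust_by(p)
        assert np.all((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0 + 1e-12))
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=12),
    st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=12),
)
def test_mann_whitney_u_complement_holds_for_arbitrary_samples(a, b):
    u_ab, p_ab = mann_whitney_u(a, b)
    u_ba, p_ba = mann_whitney_u(b, a)
    assert u_ab + u_ba == pytest.approx(len(a) * len(b))
    assert p_ab == pytest.approx(p_ba)


class TestNormalityCheck:
    def test_large_normal_sample_rarely_flagged(self):
        flags = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            flag, _ = normality_check(rng.normal(size=5000))
            flags += flag
        assert flags / 200 <= 0.09  # ~alpha, with Monte-Carlo slack

    def test_skewed_sample_flagged(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            flag, _ = normality_check(rng.lognormal(0, 1.0, size=50))
            hits += flag
        assert hits / 50 >= 0.95

    def test_constant_sample_degenerate(self):
        flag, p = normality_check([2.0, 2.0, 2.0, 2.0])
        assert flag

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])


class TestPercentChange:
    @pytest.mark.parametrize(
        "control,tag,expected",
        [
            (0.066, 0.055, -17),  # medium-tag speed change
            (1.40, 2.59, 85),  # heavy-tag rest-duration change
            (1.0, 1.0, 0),
        ],
    )
    def test_reported_rounding(self, control, tag, expected):
        assert round(percent_change(control, tag)) == expected

    def test_zero_control_flagged(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)


class TestCompareToControl:
    def test_pooled_battery_has_54_tests(self):
        table = synthetic_properties_table(seed=1, n_per_cat=12)
        comp = compare_to_control(table, stratify="pooled")
        assert len(comp) == 54  # 6 properties x 3 days x 3 tag categories
        assert (comp["p_adjusted"] >= comp["p_raw"] - 1e-12).all()
        assert comp["p_adjusted"].le(1).all()

    def test_stratified_battery_has_162_tests(self):
        table = synthetic_properties_table(seed=1, n_per_cat=12)
        comp = compare_to_control(table, stratify="by_temperature")
        assert len(comp) == 162

    def test_duplicated_control_rows_never_significant(self):
        table = synthetic_properties_table(seed=2, n_per_cat=10)
        control = table[table["weight_category"] == "control"]
        clones = []
        for cat in ("light", "medium", "heavy"):
            clone = control.copy()
            clone["weight_category"] = cat
            clone["cricket_id"] = cat + clone["cricket_id"]
            clones.append(clone)
        table = pd.concat([control] + clones, ignore_index=True)
        comp = compare_to_control(table)
        assert comp["p_adjusted"].eq(1.0).all()
        assert not comp["significant"].any()

    def test_missing_control_errors(self):
        table = synthetic_properties_table(seed=1, n_per_cat=6)
        with pytest.raises(ValueError, match="control"):
            compare_to_control(table[table["weight_category"] != "control"])

    def test_single_temperature_stratified_equals_pooled(self):
        table = synthetic_properties_table(seed=5, n_per_cat=12)
        low = table[table["temperature_category"] == "low"]
        strat = compare_to_control(low, stratify="by_temperature")
        pooled = compare_to_control(low, stratify="pooled")
        assert np.allclose(strat["p_adjusted"], pooled["p_adjusted"])
        assert np.allclose(strat["u_statistic"], pooled["u_statistic"])

    def test_medians_table_shape(self):
        table = synthetic_properties_table(seed=1, n_per_cat=8)
        med = medians_table(table)
        assert med.shape == (18, 4)  # 3 days x 6 properties, 4 categories
        assert list(med.columns) == ["control", "light", "medium", "heavy"]


class TestSlopeAnalysis:
    def _table(self, values_by_day, cat="control", cid="c0"):
        rows = []
        for day, v in values_by_day.items():
            rows.append(
                {
                    "cricket_id": cid,
                    "weight_category": cat,
                    "day": day,
                    "movementSpeed": v,
                }
            )
        return pd.DataFrame(rows)

    def test_exact_line_slope(self):
        table = pd.concat(
            [
                self._table({1: 10, 2: 12, 3: 14}, "heavy", "h0"),
                self._table({1: 1, 2: 1, 3: 1}, "control", "c0"),
            ]
        )
        slopes, _ = slope_analysis(table, "movementSpeed")
        heavy = slopes[slopes["weight_category"] == "heavy"]["slope"].iloc[0]
        assert heavy == pytest.approx(2.0)

    def test_constant_individuals_give_zero_slopes_and_p_one(self):
        parts = []
        for i in range(5):
            parts.append(self._table({1: 3, 2: 3, 3: 3}, "control", f"c{i}"))
            parts.append(self._table({1: 5, 2: 5, 3: 5}, "heavy", f"h{i}"))
        slopes, tests = slope_analysis(pd.concat(parts), "movementSpeed")
        assert np.allclose(slopes["slope"], 0.0)
        assert tests["p_value"].eq(1.0).all()

    def test_declining_heavy_arm_detected(self):
        # heavy individuals lose ~20% speed per day, controls stay flat
        detections = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            parts = []
            for i in range(15):
                base = 0.066 * rng.lognormal(0, 0.15)
                parts.append(
                    self._table(
                        {d: base * (0.8 ** (d - 1)) * rng.lognormal(0, 0.05) for d in (1, 2, 3)},
                        "heavy",
                        f"h{i}",
                    )
                )
            for i in range(45):
                base = 0.066 * rng.lognormal(0, 0.15)
                parts.append(
                    self._table(
                        {d: base * rng.lognormal(0, 0.05) for d in (1, 2, 3)},
                        "control",
                        f"c{i}",
                    )
                )
            _, tests = slope_analysis(pd.concat(parts), "movementSpeed")
            detections += (tests["p_value"] < 0.05).iloc[0]
        assert detections / n_rep >= 0.8


class TestBodyMass:
    def _meta(self, weights):
        rows = []
        for cid, per_day in weights.items():
            for day, w in per_day.items():
                rows.append(
                    {
                        "cricket_id": cid,
                        "weight_category": "control",
                        "day": day,
                        "animal_weight_mg": w,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_weights_give_p_one(self):
        meta = self._meta({f"c{i}": {1: 700, 2: 700, 3: 700} for i in range(10)})
        res = body_mass_tests(meta)
        overall = res[res["stratum"] == "all"]
        assert overall["p_value"].eq(1.0).all()
        assert overall["median_shift_mg"].eq(0.0).all()

    def test_constructed_22mg_increase(self):
        rng = np.random.default_rng(0)
        weights = {}
        for i in range(30):
            w1 = float(rng.normal(768, 117))
            weights[f"c{i}"] = {1: w1, 2: w1, 3: w1 + 22.0}
        all_rows = body_mass_tests(self._meta(weights))
        row12 = all_rows[(all_rows.stratum == "all") & (all_rows.day_pair == "1-2")].iloc[0]
        row23 = all_rows[(all_rows.stratum == "all") & (all_rows.day_pair == "2-3")].iloc[0]
        assert row12["p_value"] == pytest.approx(1.0)
        assert row23["p_value"] < 0.001
        assert row23["median_shift_mg"] == pytest.approx(22.0)

    def test_shift_power_at_cohort_size(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            weights = {}
            for i in range(180):
                w1 = float(rng.normal(768, 117))
                weights[f"c{i}"] = {
                    1: w1,
                    2: w1 + float(rng.normal(0, 10)),
                    3: w1 + float(rng.normal(22, 10)),
                }
            res = body_mass_tests(self._meta(weights))
            row = res[(res.stratum == "all") & (res.day_pair == "2-3")].iloc[0]
            hits += row["p_value"] < 0.001
        assert hits / n_rep >= 0.95
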