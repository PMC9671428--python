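"""Risk layer: region classification, mortality rules and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tidalcrm import risk
from tidalcrm.risk import MortalityRule

from conftest import make_synthetic_result


class TestClassifyRegion:
    @pytest.mark.parametrize("nose_dist,expected", [
        (0.2, "head"),
        (1.0, "torso"),
        (0.4, "torso"),       # boundary tie goes to torso
        (-0.005, "head"),     # marginal nose overrun counts as head
    ])
    def test_examples(self, nose_dist, expected):
        assert risk.classify_region(nose_dist) == expected

    def test_vectorized(self):
        out = risk.classify_region(np.array([0.1, 0.39, 0.4, 1.2]))
        assert list(out) == ["head", "head", "torso", "torso"]


class TestIsFatal:
    @pytest.mark.parametrize("speed,region,th,head_rule,expected", [
        (6.0, "torso", 5.1, False, True),   # over the published threshold
        (1.0, "head", 5.1, True, True),     # precautionary head rule
        (3.0, "torso", 4.0, False, False),
        (5.1, "torso", 5.1, False, False),  # strict comparison at threshold
    ])
    def test_examples(self, speed, region, th, head_rule, expected):
        rule = MortalityRule(speed_threshold_ms=th,
                             head_always_fatal=head_rule)
        assert risk.is_fatal(speed, region, rule) is expected

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0, 20), st.floats(0, 7), st.sampled_from(["head",
                                                               "torso"]))
    def test_head_rule_never_reduces_fatality(self, speed, th, region):
        base = MortalityRule(speed_threshold_ms=th)
        prec = MortalityRule(speed_threshold_ms=th, head_always_fatal=True)
        assert risk.is_fatal(speed, region, prec) >= \
            risk.is_fatal(speed, region, base)


def synthetic_result():
    """Six hand-written records over a 3x3 one-metre lattice, 10 time-lags."""
    cells = [
        # (y, z): cell (0, 0) gets 3 records, (1, 1) two, (-1, 0) one
        dict(start_y_m=0.0, start_z_m=0.0, phase_idx=0,
             collision_speed_ms=1.1, nose_distance_m=0.1),
        dict(start_y_m=0.0, start_z_m=0.0, phase_idx=1,
             collision_speed_ms=2.2, nose_distance_m=0.5),
        dict(start_y_m=0.0, start_z_m=0.0, phase_idx=2,
             collision_speed_ms=2.3, nose_distance_m=1.3),
        dict(start_y_m=1.0, start_z_m=1.0, phase_idx=0,
             collision_speed_ms=5.5, nose_distance_m=0.3),
        dict(start_y_m=1.0, start_z_m=1.0, phase_idx=5,
             collision_speed_ms=6.5, nose_distance_m=0.45),
        dict(start_y_m=-1.0, start_z_m=0.0, phase_idx=9,
             collision_speed_ms=4.0, nose_distance_m=0.4),
    ]
    return make_synthetic_result(cells, n_time_lags=10)


class TestMaps:
    def test_collision_map_values(self):
        res = synthetic_result()
        cp = risk.collision_probability_map(res)
        assert cp.value_at(0, 0) == pytest.approx(0.3)
        assert cp.value_at(1, 1) == pytest.approx(0.2)
        assert cp.value_at(-1, -1) == 0.0
        assert ((cp.values >= 0) & (cp.values <= 1)).all()

    def test_threshold_zero_equals_collision_map(self):
        res = synthetic_result()
        cp = risk.collision_probability_map(res)
        mp = risk.mortality_probability_map(res, MortalityRule(0.0))
        np.testing.assert_allclose(mp.values, cp.values)

    def test_threshold_above_max_speed(self):
        res = synthetic_result()
        mp = risk.mortality_probability_map(res, MortalityRule(10.0))
        assert (mp.values == 0).all()
        # with the head rule the limit is the head-collision probability
        mp2 = risk.mortality_probability_map(
            res, MortalityRule(10.0, head_always_fatal=True))
        assert mp2.value_at(0, 0) == pytest.approx(0.1)   # one head record
        assert mp2.value_at(1, 1) == pytest.approx(0.1)
        assert mp2.value_at(-1, 0) == 0.0                 # 0.4 m -> torso

    def test_mortality_never_exceeds_collision(self, coarse_a1r1):
        cp = risk.collision_probability_map(coarse_a1r1)
        for th in (0.0, 3.0, 5.1):
            for head_rule in (False, True):
                mp = risk.mortality_probability_map(
                    coarse_a1r1, MortalityRule(th, head_rule))
                assert (mp.values <= cp.values + 1e-12).all()
                assert (mp.values >= 0).all()


class TestThresholdSweep:
    def test_hand_enumeration(self):
        res = synthetic_result()
        df = risk.threshold_sweep(res, thresholds=range(8))
        n = len(res.instances)
        speeds = np.array([1.1, 2.2, 2.3, 5.5, 6.5, 4.0])
        heads = np.array([True, False, False, True, False, False])
        for row in df.itertuples():
            over = speeds > row.threshold_ms
            assert row.p_fatal_speed_only == pytest.approx(over.sum() / n)
            assert row.p_fatal_with_head_rule == pytest.approx(
                (over | heads).sum() / n)
            assert row.p_head_component == pytest.approx(
                (heads & ~over).sum() / n)

    def test_monotone_and_ordered(self, coarse_a1r1):
        df = risk.threshold_sweep(coarse_a1r1)
        assert (df.threshold_ms.diff().dropna() > 0).all()
        assert (df.p_fatal_speed_only.diff().dropna() <= 1e-12).all()
        assert (df.p_fatal_with_head_rule.diff().dropna() <= 1e-12).all()
        assert (df.p_fatal_with_head_rule >= df.p_fatal_speed_only).all()
        cp_overall = len(coarse_a1r1.records) / len(coarse_a1r1.instances)
        assert df.p_fatal_speed_only.iloc[0] == pytest.approx(cp_overall)
        assert (df.p_fatal_with_head_rule <= cp_overall + 1e-12).all()

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            risk.threshold_sweep(synthetic_result(), thresholds=[])


class TestSummary:
    def test_known_composition(self):
        cells = [dict(start_y_m=0.0, start_z_m=0.0, phase_idx=k,
                      collision_speed_ms=1.0,
                      nose_distance_m=0.1 if k < 4 else 0.9)
                 for k in range(10)]
        res = make_synthetic_result(cells, n_time_lags=10)
        df = risk.head_torso_summary([res])
        row = df.iloc[0]
        assert row.head_pct == 40.0
        assert row.torso_pct == 60.0
        assert row.total_collisions == 10

    def test_zero_records(self):
        res = make_synthetic_result([], n_time_lags=5)
        row = risk.head_torso_summary([res]).iloc[0]
        assert row.total_collisions == 0
        assert np.isnan(row.head_pct) and np.isnan(row.torso_pct)

    def test_percentages_sum_to_100(self, coarse_speed_series):
        df = risk.head_torso_summary(coarse_speed_series.values())
        assert np.allclose(df.head_pct + df.torso_pct, 100.0, atol=0.1)
        counts = [len(r.records) for r in coarse_speed_series.values()]
        assert list(df.total_collisions) == counts


class TestHistogram:
    def test_counts_sum_and_bins(self):
        cells = [dict(start_y_m=0.0, start_z_m=0.0, phase_idx=k,
                      collision_speed_ms=s, nose_distance_m=0.2)
                 for k, s in enumerate([1.1, 2.2, 2.3])]
        res = make_synthetic_result(cells, n_time_lags=10)
        h = risk.speed_histogram(res, bin_width_ms=1.0)
        assert h.total == 3
        counts = h.head_counts + h.torso_counts
        assert counts[1] == 1 and counts[2] == 2  # bins [1,2) and [2,3)

    def test_empty_result(self):
        h = risk.speed_histogram(make_synthetic_result([]), 1.0)
        assert h.total == 0

    def test_min_speed_at_least_approach(self, coarse_a1r1):
        h = risk.speed_histogram(coarse_a1r1, 0.5)
        v = coarse_a1r1.scenario.approach_speed_ms
        assert coarse_a1r1.records.collision_speed_ms.min() >= v
        nonzero = np.nonzero(h.head_counts + h.torso_counts)[0]
        assert h.bin_edges[nonzero[0] + 1] > v


class TestConvergence:
    def test_full_set_zero_deviation(self):
        res = synthetic_result()
        df = risk.convergence_check(res, [10])
        assert df.max_abs_cp_deviation.iloc[0] == 0.0

    def test_hand_computed_subsets(self):
        cells = [dict(start_y_m=0.0, start_z_m=0.0, phase_idx=k,
                      collision_speed_ms=1.0, nose_distance_m=0.2)
                 for k in (0, 1)]
        res = make_synthetic_result(cells, n_time_lags=4)
        # full CP = 0.5; phases {0, 2} -> 1/2 hit -> dev 0; phase {0} -> 1.0
        df = risk.convergence_check(res, [2, 1])
        assert df.max_abs_cp_deviation.tolist() == [0.0, 0.5]

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            risk.convergence_check(synthetic_result(), [0])

    def test_converged_slow_scenario(self, coarse_a1r1):
        df = risk.convergence_check(coarse_a1r1, [25])
        assert df.max_abs_cp_deviation.iloc[0] <= 0.05


def test_nose_overrun_rate():
    cells = [dict(start_y_m=0.0, start_z_m=0.0, phase_idx=k,
                  collision_speed_ms=1.0,
                  nose_distance_m=-0.001 if k == 0 else 0.5)
             for k in range(4)]
    res = make_synthetic_result(cells, n_time_lags=10)
    assert risk.nose_overrun_rate(res) == pytest.approx(25.0)
    assert risk.nose_overrun_rate(make_synthetic_result([])) == 0.0
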