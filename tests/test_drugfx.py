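import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oepsc.detect import EventRecord, detect_events, differentiate
from oepsc.drugfx import (
    ConditionSummary,
    analyze_condition,
    cumulative_event_curve,
    ecdf_events,
    effect_table,
    latency_effect_regression,
    rank_compare,
    summarize_condition,
)
from oepsc.errors import DataError, ParameterError
from oepsc.synth import DRUG_PRESETS, MonoConfig, NoiseConfig, PolyConfig, SimConfig, simulate

from conftest import kernel_sweepset


def ev(lat, slope=300.0, sweep=0):
    return EventRecord("cellX", "baseline", None, sweep, lat, slope)


class TestSummarize:
    def test_no_events_zero_rates_nan_slopes(self):
        ss = kernel_sweepset([[(2.5, 200.0)]] * 10)
        s = summarize_condition(ss, [], trough=4.72)
        assert s.events_per_episode_early == 0.0 and s.events_per_episode_late == 0.0
        assert np.isnan(s.mean_slope_early) and np.isnan(s.mean_slope_late)

    def test_rates_and_slope_means(self):
        ss = kernel_sweepset([[(2.5, 200.0)]] * 10)
        events = [ev(2.5, 300.0, sweep=i) for i in range(10)]
        s = summarize_condition(ss, events, trough=4.72)
        assert s.events_per_episode_early == pytest.approx(1.0)
        assert s.mean_slope_early == pytest.approx(300.0)
        assert s.n_events_late == 0

    def test_kor_scaling_reduces_both_populations(self):
        base_cfg = SimConfig(seed=31, n_sweeps=200)
        drug_cfg = SimConfig(
            seed=32, n_sweeps=200, drug=DRUG_PRESETS["KOR"], condition_preset="agonist"
        )
        base_ss, _ = simulate(base_cfg)
        drug_ss, _ = simulate(drug_cfg)
        sb, _ = analyze_condition(base_ss, trough=4.5)
        sd, _ = analyze_condition(drug_ss, trough=4.5)
        early_ratio = sd.events_per_episode_early / sb.events_per_episode_early
        late_ratio = sd.events_per_episode_late / sb.events_per_episode_late
        # mono_scale 0.2 propagates to the recurrent drive; both populations drop ~80%
        assert early_ratio == pytest.approx(0.2, abs=0.1)
        assert late_ratio == pytest.approx(0.2, abs=0.1)


class TestEffectTable:
    def summaries(self):
        def s(cell, cond, peak, drug=None):
            return ConditionSummary(cell, cond, drug, peak, 2.5, 1.0, 1.0, 300.0, 150.0, 10, 10, 10)

        return [
            s("a", "baseline", 800.0),
            s("a", "agonist", 160.0, "U69"),
            s("b", "baseline", 500.0),
            s("b", "agonist", 500.0, "U69"),
        ]

    def test_pct_reduction_rows(self):
        table = effect_table(self.summaries())
        assert len(table) == 2
        row_a = table[table.cell_id == "a"].iloc[0]
        assert row_a.pct_reduction == pytest.approx(80.0)
        row_b = table[table.cell_id == "b"].iloc[0]
        assert row_b.pct_reduction == pytest.approx(0.0)

    def test_missing_baseline_rejected(self):
        bad = self.summaries()[1:2]
        with pytest.raises(DataError):
            effect_table(bad)

    def test_antagonist_optional(self):
        table = effect_table(self.summaries())
        assert set(table.condition) == {"agonist"}


class TestEcdf:
    def test_equal_steps(self):
        out = ecdf_events({"baseline": [1.0, 2.0, 3.0]})
        x, y = out["baseline"]
        assert np.allclose(y, [1 / 3, 2 / 3, 1.0])

    def test_duplicate_latency_single_step(self):
        x, y = ecdf_events({"c": [2.0, 2.0, 5.0]})["c"]
        assert np.allclose(x, [2.0, 5.0]) and np.allclose(y, [2 / 3, 1.0])

    def test_terminal_value_one_and_empty_rejected(self):
        x, y = ecdf_events({"c": np.random.default_rng(0).uniform(0, 10, 50)})["c"]
        assert y[-1] == pytest.approx(1.0)
        with pytest.raises(DataError):
            ecdf_events({"c": []})

    def test_cumulative_curve_per_episode(self):
        events = [ev(2.0, sweep=i) for i in range(10)] + [ev(8.0, sweep=i) for i in range(5)]
        grid, curve = cumulative_event_curve(events, n_episodes=10)
        assert curve[-1] == pytest.approx(1.5)
        assert curve[np.searchsorted(grid, 5.0)] == pytest.approx(1.0)


class TestRegression:
    def test_colinear_points(self):
        res = latency_effect_regression([2.0, 4.0, 6.0, 8.0], [20.0, 40.0, 60.0, 80.0])
        assert res.slope == pytest.approx(10.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response_flat(self):
        res = latency_effect_regression([2.0, 4.0, 6.0], [50.0, 50.0, 50.0])
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_zero_latency_variance_rejected(self):
        with pytest.raises(DataError):
            latency_effect_regression([3.0, 3.0, 3.0], [10.0, 20.0, 30.0])

    def test_known_slope_recovered(self):
        rng = np.random.default_rng(4)
        lat = rng.uniform(2, 8, 16)
        red = 8.0 * lat + rng.normal(0, 5, 16)
        res = latency_effect_regression(lat, red)
        se = res.slope / max(np.sqrt(stats.t.ppf(0.975, 14)), 1e-9)
        assert res.slope == pytest.approx(8.0, abs=3.0)
        assert res.p_value < 0.05


class TestRankCompare:
    def test_identical_groups_h_near_zero(self):
        res = rank_compare([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        assert res.h == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_matches_brute_force_ranks(self):
        groups = [[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]]
        res = rank_compare(groups)
        # brute-force: ranks 1..6, mean ranks 2 and 5
        n = 6
        h_brute = 12 / (n * (n + 1)) * (3 * 2**2 + 3 * 5**2) - 3 * (n + 1)
        assert res.h == pytest.approx(h_brute, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        groups = [[1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 4.0, 4.0], [0.5, 4.0, 6.0, 6.0]]
        res = rank_compare(groups)
        h_ref, p_ref = stats.kruskal(*groups)
        assert res.h == pytest.approx(h_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_dunn_pairwise_shape_and_symmetry(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        res = rank_compare(groups)
        assert len(res.pairwise) == 3
        assert (res.pairwise.p_adjusted <= 1.0).all()
        z01 = res.pairwise.query("group_i == 0 and group_j == 1").z.iloc[0]
        z12 = res.pairwise.query("group_i == 1 and group_j == 2").z.iloc[0]
        assert z01 == pytest.approx(z12)  # equally spaced mean ranks

    def test_degenerate_identical_values_rejected(self):
        with pytest.raises(DataError):
            rank_compare([[1.0, 1.0], [1.0, 1.0]])

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            rank_compare([[1.0], [2.0, 3.0]])
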