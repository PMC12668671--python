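"""Phase segmentation, classification, unit maps and statistic extraction."""

import numpy as np
import pytest

from riskexplore import (
    MinuteRecord,
    PhaseSummary,
    StatVector,
    classify_group,
    duration_to_seconds,
    extract_statistics,
    fit_boxcar,
    model_statistics,
    turns_to_minutes,
)
from riskexplore.phases import BRAVE, INTERMEDIATE, TIMID
from riskexplore.simulate import Trajectory, TurnRecord
from riskexplore import Action, Loc


class TestUnitMaps:
    def test_duration_endpoints(self):
        assert duration_to_seconds(2) == pytest.approx(0.75)
        assert duration_to_seconds(4) == pytest.approx(3.75)

    def test_session_length(self):
        assert turns_to_minutes(200) == pytest.approx(100.0)

    def test_duration_map_linear_and_invertible(self):
        for d in np.linspace(2.0, 4.0, 9):
            s = duration_to_seconds(d)
            assert (s - 0.75) / 1.5 + 2.0 == pytest.approx(d)

    @pytest.mark.parametrize("d", [1.0, 1.99, 4.01, 5.0])
    def test_duration_domain(self, d):
        with pytest.raises(ValueError):
            duration_to_seconds(d)


class TestBoxcar:
    def test_noiseless_step(self):
        k, before, after = fit_boxcar([10, 10, 10, 0, 0])
        assert (k, before, after) == (3, 10.0, 0.0)

    def test_constant_series_has_no_change_point(self):
        k, before, after = fit_boxcar([4.0] * 12)
        assert k is None
        assert before == after == 4.0

    def test_recovers_change_point_under_noise(self):
        rng = np.random.default_rng(42)
        truth = np.r_[np.full(30, 25.0), np.full(70, 5.0)]
        series = truth + rng.normal(0, 1.0, 100)
        k, before, after = fit_boxcar(series)
        assert k == 30
        assert before == pytest.approx(25.0, abs=1.0)
        assert after == pytest.approx(5.0, abs=1.0)

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            fit_boxcar([1.0])


def _record(g_con, g_cau=None, n=100):
    g_con = np.asarray(g_con, dtype=float)
    if g_cau is None:
        g_cau = np.zeros_like(g_con)
    return MinuteRecord(
        pct_cautious=g_cau,
        pct_confident=g_con,
        duration_s=np.ones(n),
        bouts_per_min=np.ones(n),
    )


class TestClassify:
    def test_no_confident_time_is_timid(self):
        assert classify_group(_record(np.zeros(100))) == TIMID

    def test_peak_then_decay_is_brave(self):
        g = np.zeros(100)
        g[20:30] = 40.0  # first 10 min of confident approach
        g[30:] = 20.0  # steady state, y = 2
        assert classify_group(_record(g)) == BRAVE

    def test_growing_confident_time_is_intermediate(self):
        g = np.zeros(100)
        g[20:30] = 16.0
        g[30:] = 20.0  # y = 0.8
        assert classify_group(_record(g)) == INTERMEDIATE

    def test_flat_confident_boundary_goes_to_intermediate(self):
        g = np.zeros(100)
        g[20:] = 30.0  # y = 1 exactly
        assert classify_group(_record(g)) == INTERMEDIATE

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="minutes"):
            classify_group(_record(np.zeros(15), n=15))


class TestExtractStatistics:
    def test_intermediate_frequency_ratio_clamped(self):
        phases = PhaseSummary(
            group=INTERMEDIATE, t1=20.0,
            durations={"cautious": 1.0, "confident": 2.0},
            frequencies={"cautious": 2.0, "confident": 4.0},  # ratio 0.5 -> clamp
        )
        sv = extract_statistics(phases)
        assert sv.values[-1] == 1.0

    def test_brave_ratio_is_simple_division(self):
        phases = PhaseSummary(
            group=BRAVE, t1=10.0, t2=30.0,
            durations={"cautious": 1.0, "confident_peak": 3.0, "confident_steady": 3.0},
            frequencies={"cautious": 5.0, "confident_peak": 6.0, "confident_steady": 2.0},
        )
        sv = extract_statistics(phases)
        assert sv.values[-1] == pytest.approx(3.0)
        assert sv.names == (
            "t_cautious_to_confident", "t_peak_to_steady",
            "d_cautious", "d_peak_confident", "f_peak_over_steady",
        )

    def test_missing_phase_is_named_in_error(self):
        phases = PhaseSummary(
            group=TIMID, t2=25.0,
            durations={"cautious_peak": 1.5},
            frequencies={"cautious_peak": 4.0, "cautious_steady": 1.5},
        )
        with pytest.raises(ValueError, match="cautious_steady"):
            extract_statistics(phases)

    def test_group_vector_sizes(self):
        assert len(StatVector(BRAVE, np.zeros(5)).names) == 5
        with pytest.raises(ValueError):
            StatVector(TIMID, np.zeros(5))
        with pytest.raises(ValueError):
            StatVector("fearless", np.zeros(4))


def _model_traj(bout_plan, n_turns=200):
    """Build a trajectory from a list of (start, length, approach, nest_gap)."""
    records = []
    t = 0

    def nest(turns):
        nonlocal t
        for _ in range(turns):
            records.append(TurnRecord(t, Loc.NEST, 0, Action.STAY_NEST, 1.0))
            t += 1

    for start, length, approach in bout_plan:
        nest(start - t)  # fills up to turn start-1; that turn carries the approach
        records[-1] = TurnRecord(
            records[-1].turn, Loc.NEST, 0,
            Action.APPROACH_CAUTIOUS if approach == "cautious" else Action.APPROACH_CONFIDENT,
            1.0,
        )
        loc = Loc.CAUTIOUS_OBJECT if approach == "cautious" else Loc.CONFIDENT_OBJECT
        for tau in range(1, length + 1):
            act = Action.STAY_OBJECT if tau < length else Action.RETREAT
            records.append(TurnRecord(t, loc, tau, act, 1.0))
            t += 1
        records.append(TurnRecord(t, Loc.RETREAT, 0, None, 1.0))
        t += 1
    nest(n_turns - t)
    return Trajectory(records=records)


class TestModelStatistics:
    def test_no_bouts_is_degenerate_maximally_timid(self):
        traj = _model_traj([], n_turns=40)
        stats, phases = model_statistics(traj)
        assert stats is None
        assert phases.group == TIMID
        assert phases.degenerate

    def test_confident_transition_turn_maps_to_minutes(self):
        # cautious bouts every 4 turns, then confident from turn 50
        plan = [(1 + 4 * i, 2, "cautious") for i in range(12)]
        plan += [(50 + 4 * i, 2, "confident") for i in range(10)]
        plan += [(100 + 10 * i, 2, "confident") for i in range(9)]
        stats, phases = model_statistics(_model_traj(plan))
        assert phases.group == BRAVE
        assert stats.as_dict()["t_cautious_to_confident"] == pytest.approx(25.0)

    def test_peak_phase_frequency_from_period(self):
        # alternating 1 nest turn / 2 object turns: period 4 turns -> 0.5/min,
        # then period-10 cycles: the ratio is the period ratio
        plan = [(1 + 4 * i, 2, "cautious") for i in range(20)]
        plan += [(87 + 10 * i, 2, "cautious") for i in range(11)]
        stats, phases = model_statistics(_model_traj(plan))
        assert phases.group == TIMID
        assert phases.frequencies["cautious_peak"] == pytest.approx(0.5)
        assert stats.as_dict()["f_peak_over_steady"] == pytest.approx(10 / 4)

    def test_intermediate_has_no_second_transition(self):
        plan = [(1 + 4 * i, 2, "cautious") for i in range(10)]
        plan += [(41 + 5 * i, 3, "confident") for i in range(25)]
        stats, phases = model_statistics(_model_traj(plan, n_turns=170))
        assert phases.group == INTERMEDIATE
        assert phases.t2 is None
        assert len(stats.values) == 4

    def test_timid_vector_has_four_entries(self):
        from riskexplore.presets import TIMID_PARAMS
        from riskexplore import simulate

        stats, phases = model_statistics(simulate(TIMID_PARAMS))
        assert phases.group == TIMID
        assert len(stats.values) == 4
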