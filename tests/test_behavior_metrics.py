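import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trajectory, random_trajectory
from oracles import bolt_runs_oracle, path_length_oracle

from zfpheno import (
    ActivityThresholds,
    BoltParams,
    Trajectory,
    ValidationError,
    classify_activity,
    compute_velocity,
    epoch_metrics,
    locomotor_profile,
    segment_bolts,
    standard_schedule,
    summarize_larva,
)
from zfpheno.behavior_metrics import VelocitySeries, smooth_velocity, summaries_table
from zfpheno.trajectory_io import CohortDataset


def vseries(v, rate_hz=10.0):
    v = np.asarray(v, dtype=float)
    dt = 1.0 / rate_hz
    return VelocitySeries(t_mid=np.arange(len(v)) * dt + dt / 2, v=v, dt=dt)


class TestComputeVelocity:
    def test_stationary(self):
        tr = make_trajectory(np.zeros(9))
        assert np.all(compute_velocity(tr).v == 0)

    def test_three_four_five_step(self):
        # One step of (0.03, 0.04) mm over 0.1 s -> 0.05 mm / 0.1 s = 0.5 mm/s
        tr = Trajectory("w", "control", 10.0, [0.0, 0.1], [0.0, 0.03], [0.0, 0.04])
        assert compute_velocity(tr).v[0] == pytest.approx(0.5)

    def test_total_distance_matches_pairwise_oracle(self, rng):
        tr = random_trajectory(rng, n_intervals=300)
        vel = compute_velocity(tr)
        assert np.sum(vel.v) * vel.dt == pytest.approx(
            path_length_oracle(tr.x, tr.y), rel=1e-12
        )


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "v,state,phase",
        [
            (0.05, "inactive", "stationary"),
            (0.1, "inactive", "stationary"),  # boundary: <= 0.1 is inactive
            (0.11, "active", "normal"),
            (1.2, "active", "normal"),  # boundary: <= 1.2 is still normal
            (2.0, "active", "abrupt"),
        ],
    )
    def test_thresholds(self, thresholds, v, state, phase):
        s, p = classify_activity(vseries([v]), thresholds)
        assert (s[0], p[0]) == (state, phase)

    def test_invalid_threshold_order(self):
        with pytest.raises(ValidationError):
            ActivityThresholds(theta_active=1.5, theta_abrupt=1.2)


class TestSegmentBolts:
    def test_no_movement(self, thresholds):
        assert segment_bolts(vseries(np.zeros(50)), thresholds) == []

    def test_short_trailing_run_discarded(self, thresholds):
        # 10 Hz: 5 inactive, 6 active, 4 inactive, 1 active; min 0.2 s, gap 0.1 s
        v = [0] * 5 + [0.5] * 6 + [0] * 4 + [0.5]
        events = segment_bolts(vseries(v), thresholds, BoltParams(0.2, 0.1))
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(0.5)
        assert events[0].end_s == pytest.approx(1.1)

    def test_single_gap_interval_merged(self, thresholds):
        v = [0.5] * 3 + [0.0] + [0.5] * 3
        events = segment_bolts(vseries(v), thresholds, BoltParams(0.2, 0.1))
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(0.7)
        # distance accumulates over the whole merged span, gap included
        assert events[0].distance_mm == pytest.approx(6 * 0.5 * 0.1)

    def test_gap_beyond_merge_window_not_merged(self, thresholds):
        v = [0.5] * 3 + [0.0, 0.0] + [0.5] * 3
        events = segment_bolts(vseries(v), thresholds, BoltParams(0.0, 0.1))
        assert len(events) == 2

    @given(
        pattern=st.lists(st.sampled_from([0.0, 0.5, 2.0]), min_size=1, max_size=30),
        min_dur=st.sampled_from([0.0, 0.2, 0.4]),
        gap=st.sampled_from([0.0, 0.1, 0.3]),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_run_length_oracle(self, pattern, min_dur, gap):
        events = segment_bolts(vseries(pattern), ActivityThresholds(), BoltParams(min_dur, gap))
        expected = bolt_runs_oracle(pattern, 0.1, 0.1, min_dur, gap)
        assert len(events) == len(expected)
        for ev, (a, b) in zip(events, expected):
            assert ev.start_s == pytest.approx(a * 0.1)
            assert ev.end_s == pytest.approx(b * 0.1)
            assert ev.distance_mm == pytest.approx(sum(pattern[a:b]) * 0.1)
            assert ev.peak_v_mms == pytest.approx(max(pattern[a:b]))

    @given(
        pattern=st.lists(st.sampled_from([0.0, 0.05, 0.5, 2.0]), min_size=1, max_size=30),
        theta_lo=st.floats(0.01, 1.0),
        theta_hi=st.floats(1.01, 1.9),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_threshold_never_increases_activity(self, pattern, theta_lo, theta_hi):
        vs = vseries(pattern)
        s_lo, _ = classify_activity(vs, ActivityThresholds(theta_lo, 2.0))
        s_hi, _ = classify_activity(vs, ActivityThresholds(theta_hi, 2.0))
        assert np.mean(s_hi == "active") <= np.mean(s_lo == "active")

    @given(
        pattern=st.lists(st.sampled_from([0.0, 0.5, 2.0]), min_size=1, max_size=30),
        theta_lo=st.floats(0.01, 0.2),
        theta_hi=st.floats(0.21, 0.45),
        min_dur=st.sampled_from([0.0, 0.2]),
        gap=st.sampled_from([0.0, 0.1]),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_threshold_below_bolt_speeds_never_adds_bolts(
        self, pattern, theta_lo, theta_hi, min_dur, gap
    ):
        # Monotonicity holds when the threshold stays below the support of
        # within-bolt speeds (the operating regime: jitter << bolt speed).
        # A threshold placed *inside* the speed distribution can split a run
        # whose interior dips between the two cuts, so the unrestricted claim
        # is false; activity fraction alone is monotone for any threshold.
        vs = vseries(pattern)
        n_lo = len(segment_bolts(vs, ActivityThresholds(theta_lo, 2.0), BoltParams(min_dur, gap)))
        n_hi = len(segment_bolts(vs, ActivityThresholds(theta_hi, 2.0), BoltParams(min_dur, gap)))
        assert n_hi <= n_lo


class TestSummarizeLarva:
    def test_immobile_larva(self):
        sched = standard_schedule(1, 5.0, 5.0)
        tr = make_trajectory(np.zeros(100), rate_hz=10.0)
        s = summarize_larva(tr, sched)
        assert s.total_distance_mm == 0
        assert s.n_bolts == 0
        assert s.active_fraction == 0
        assert np.isnan(s.overall.bolt_duration_s)
        assert np.isnan(s.overall.distance_per_bolt_mm)
        assert np.isnan(s.bolt_interval_s)

    def test_two_bolt_interval(self):
        # bolt 1 spans [1.0, 2.0] s, bolt 2 spans [5.0, 6.0] s -> gap 3.0 s
        sched = standard_schedule(1, 5.0, 5.0)
        v = np.zeros(100)
        v[10:20] = 1.0
        v[50:60] = 1.0
        s = summarize_larva(make_trajectory(v, rate_hz=10.0), sched)
        assert s.n_bolts == 2
        assert s.bolt_interval_s == pytest.approx(3.0)
        # one bolt per condition (midpoints 1.5 s -> light, 5.5 s -> dark)
        assert s.per_condition["light"].n_bolts == 1
        assert s.per_condition["dark"].n_bolts == 1

    def test_activity_fractions_partition(self, rng, schedule):
        tr = random_trajectory(rng, n_intervals=4500, rate_hz=25.0, scale=5.0)
        s = summarize_larva(tr, schedule)
        assert s.active_fraction + s.inactive_fraction == pytest.approx(1.0)
        for m in s.per_condition.values():
            assert m.active_fraction + m.inactive_fraction == pytest.approx(1.0)

    def test_bolt_distance_bounded_by_total(self, rng, schedule):
        tr = random_trajectory(rng, n_intervals=4500, rate_hz=25.0, scale=5.0)
        s = summarize_larva(tr, schedule)
        bolt_total = sum(b.distance_mm for b in s.bolts)
        assert bolt_total <= s.total_distance_mm + 1e-9

    def test_scale_equivariance(self, rng, schedule):
        tr = random_trajectory(rng, n_intervals=4500, rate_hz=25.0, scale=5.0)
        c = 3.7
        scaled = Trajectory(tr.well_id, tr.group, tr.rate_hz, tr.t, c * tr.x, c * tr.y)
        # rescale thresholds too so segmentation picks identical intervals
        thr = ActivityThresholds(0.1 * c, 1.2 * c)
        s1 = summarize_larva(tr, schedule)
        s2 = summarize_larva(scaled, schedule, thr)
        assert s2.total_distance_mm == pytest.approx(c * s1.total_distance_mm)
        for b1, b2 in zip(s1.bolts, s2.bolts):
            assert b2.distance_mm == pytest.approx(c * b1.distance_mm)


class TestEpochMetrics:
    def test_light_dark_distance_conservation(self, rng, schedule):
        summaries = [
            summarize_larva(random_trajectory(rng, 4500, 25.0, scale=5.0, well_id=f"w{i}"), schedule)
            for i in range(4)
        ]
        table = epoch_metrics(summaries)
        dist = table[table["metric"] == "total_distance_mm"]
        for s in summaries:
            parts = dist[dist["well_id"] == s.well_id]["value"].sum()
            assert parts == pytest.approx(s.total_distance_mm, abs=1e-9)

    def test_movement_only_in_light(self):
        sched = standard_schedule(1, 5.0, 5.0)
        v = np.zeros(100)
        v[10:30] = 1.0  # 1.0-3.0 s, all within the light epoch
        s = summarize_larva(make_trajectory(v, rate_hz=10.0), sched)
        assert s.per_condition["dark"].total_distance_mm == 0
        assert s.per_condition["light"].total_distance_mm == pytest.approx(s.total_distance_mm)

    def test_two_condition_rows_per_larva_per_metric(self, rng, schedule):
        summaries = [
            summarize_larva(random_trajectory(rng, 4500, 25.0, well_id=f"w{i}"), schedule)
            for i in range(3)
        ]
        table = epoch_metrics(summaries)
        counts = table.groupby(["well_id", "metric"])["condition"].nunique()
        assert (counts == 2).all()

    def test_mixed_schedules_rejected(self, rng):
        s1 = standard_schedule(3, 30.0, 30.0)
        s2 = standard_schedule(2, 45.0, 45.0)
        a = summarize_larva(random_trajectory(rng, 4500, 25.0, well_id="a"), s1)
        b = summarize_larva(random_trajectory(rng, 4500, 25.0, well_id="b"), s2)
        with pytest.raises(ValidationError, match="schedule"):
            epoch_metrics([a, b])


class TestLocomotorProfile:
    def test_immobile_group_zero_profile(self, schedule):
        trs = [
            make_trajectory(np.zeros(4500), rate_hz=25.0, well_id=f"w{i}") for i in range(3)
        ]
        cohort = CohortDataset(trs, schedule)
        prof = locomotor_profile(cohort, "control")
        assert np.all(prof.mean_distance_mm == 0)

    def test_standard_assay_has_180_bins(self, demo_cohort):
        prof = locomotor_profile(demo_cohort, "control")
        assert len(prof.mean_distance_mm) == 180

    def test_profile_sums_to_mean_total_distance(self, demo_cohort):
        prof = locomotor_profile(demo_cohort, "treated")
        totals = [
            summarize_larva(tr, demo_cohort.schedule).total_distance_mm
            for tr in demo_cohort.by_group("treated")
        ]
        assert prof.mean_distance_mm.sum() == pytest.approx(np.mean(totals), rel=1e-9)

    def test_empty_group_rejected(self, schedule):
        trs = [make_trajectory(np.zeros(4500), rate_hz=25.0, well_id="w0")]
        cohort = CohortDataset(trs, schedule)
        with pytest.raises(ValidationError, match="treated"):
            locomotor_profile(cohort, "treated")

    def test_bin_must_divide_span(self, demo_cohort):
        with pytest.raises(ValidationError, match="divide"):
            locomotor_profile(demo_cohort, "control", bin_s=7.0)


class TestSmoothing:
    def test_window_must_be_odd(self):
        with pytest.raises(ValidationError):
            smooth_velocity(vseries([1.0, 2.0, 3.0]), 2)

    def test_interior_average(self):
        sm = smooth_velocity(vseries([0.0, 3.0, 0.0, 3.0, 0.0]), 3)
        assert sm.v[2] == pytest.approx(2.0)

    def test_summary_distance_uses_raw_velocity(self, rng, schedule):
        tr = random_trajectory(rng, 4500, 25.0, scale=5.0)
        s_raw = summarize_larva(tr, schedule)
        s_smooth = summarize_larva(tr, schedule, smooth_window=5)
        assert s_smooth.total_distance_mm == pytest.approx(s_raw.total_distance_mm)


def test_summaries_table_one_row_per_larva(demo_cohort):
    summaries = [summarize_larva(tr, demo_cohort.schedule) for tr in demo_cohort.larvae]
    table = summaries_table(summaries)
    assert len(table) == 24
    assert set(table["group"]) == {"control", "treated"}
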