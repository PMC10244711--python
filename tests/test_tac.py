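import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdopakin import (
    FrameSchedule,
    SubjectMeta,
    TimeActivityCurve,
    ValidationError,
    build_schedule,
    compute_suv,
    cumulative_integral,
    decay_correct,
    decay_uncorrect,
    find_pseudo_equilibrium,
    suv_ratio,
)
from fdopakin.tac import STUDY_FRAME_DURATIONS_S


class TestBuildSchedule:
    @pytest.mark.parametrize(
        "durations, starts, mids, total",
        [
            ([60.0], [0.0], [30.0], 60.0),
            ([10.0, 20.0, 30.0], [0.0, 10.0, 30.0], [5.0, 20.0, 45.0], 60.0),
        ],
    )
    def test_contiguous_arithmetic(self, durations, starts, mids, total):
        s = build_schedule(durations)
        assert s.frame_starts.tolist() == starts
        assert s.mid_times.tolist() == mids
        assert s.total_duration == total

    def test_study_schedule_spans_two_hours(self):
        s = build_schedule(STUDY_FRAME_DURATIONS_S)
        assert s.n_frames == 33
        assert s.total_duration == 7200.0

    @pytest.mark.parametrize("bad", [[], [0.0], [30.0, -1.0]])
    def test_invalid_durations_rejected(self, bad):
        with pytest.raises(ValidationError):
            build_schedule(bad)

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValidationError):
            FrameSchedule(np.array([0.0, 10.0]), np.array([20.0, 10.0]))


class TestDecayCorrection:
    def test_one_half_life_doubles(self):
        s = build_schedule([10.0, 10.0])
        raw = TimeActivityCurve(s, np.array([1.0, 1.0]), decay_corrected=False)
        # half-life equal to the first mid-time: that frame exactly doubles
        out = decay_correct(raw, half_life_s=5.0, to_time_s=0.0)
        assert out.activity[0] == pytest.approx(2.0)
        assert out.decay_corrected

    def test_correcting_to_own_midtime_is_identity(self):
        s = build_schedule([60.0])
        raw = TimeActivityCurve(s, np.array([3.0]), decay_corrected=False)
        out = decay_correct(raw, half_life_s=100.0, to_time_s=30.0)
        assert out.activity[0] == pytest.approx(3.0)

    def test_round_trip(self, sched):
        rng = np.random.default_rng(0)
        tac = TimeActivityCurve(sched, rng.uniform(1, 50, sched.n_frames))
        back = decay_correct(decay_uncorrect(tac))
        np.testing.assert_allclose(back.activity, tac.activity, rtol=1e-12)

    def test_double_correction_rejected(self, flat_tac):
        with pytest.raises(ValidationError):
            decay_correct(flat_tac)


class TestCumulativeIntegral:
    def test_constant_activity_closed_form(self):
        s = FrameSchedule(np.array([5.0, 15.0, 25.0]), np.array([10.0, 10.0, 10.0]))
        tac = TimeActivityCurve(s, np.ones(3))
        np.testing.assert_allclose(cumulative_integral(tac), [5.0, 15.0, 25.0])

    def test_zero_tac(self, sched):
        tac = TimeActivityCurve(sched, np.zeros(sched.n_frames))
        assert np.all(cumulative_integral(tac) == 0.0)

    def test_linear_ramp_matches_analytic(self):
        s = build_schedule([5.0] * 120)  # 600 s of 5 s frames
        a = 0.02
        tac = TimeActivityCurve(s, a * s.mid_times)
        expected = a * s.mid_times**2 / 2.0
        np.testing.assert_allclose(cumulative_integral(tac), expected, rtol=0.02)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=30))
    def test_monotone_and_linear(self, values):
        s = build_schedule([30.0] * len(values))
        v = np.asarray(values)
        tac = TimeActivityCurve(s, v)
        integral = cumulative_integral(tac)
        assert np.all(np.diff(integral) >= -1e-12)  # monotone for non-negative TACs
        double = cumulative_integral(TimeActivityCurve(s, 2 * v))
        np.testing.assert_allclose(double, 2 * integral, atol=1e-9)


class TestSUV:
    META = SubjectMeta("r1", "WT", 5, weight_kg=0.37, injected_dose_MBq=18.5)

    def test_printed_formula_example(self, sched):
        tac = TimeActivityCurve(sched, np.full(sched.n_frames, 5.0))
        suv = compute_suv(tac, self.META)
        np.testing.assert_allclose(suv.suv, 0.1)

    def test_dose_activity_rescaling_invariance(self, sched):
        tac = TimeActivityCurve(sched, np.full(sched.n_frames, 5.0))
        meta2 = SubjectMeta("r1", "WT", 5, weight_kg=0.37, injected_dose_MBq=3 * 18.5)
        tac2 = TimeActivityCurve(sched, 3 * tac.activity)
        np.testing.assert_allclose(compute_suv(tac2, meta2).suv, compute_suv(tac, self.META).suv)

    def test_zero_activity(self, sched):
        tac = TimeActivityCurve(sched, np.zeros(sched.n_frames))
        assert np.all(compute_suv(tac, self.META).suv == 0.0)

    @pytest.mark.parametrize("weight, dose", [(0.0, 18.5), (-1.0, 18.5), (0.37, 0.0)])
    def test_invalid_meta_rejected(self, weight, dose):
        with pytest.raises(ValidationError):
            SubjectMeta("r1", "WT", 5, weight_kg=weight, injected_dose_MBq=dose)

    def test_suvr_is_activity_ratio(self, striatum_tac, cerebellum_tac):
        # dose/weight cancel: SUVr equals the raw activity ratio
        s = compute_suv(striatum_tac, self.META)
        c = compute_suv(cerebellum_tac, self.META)
        keep = cerebellum_tac.activity > 0
        np.testing.assert_allclose(
            suv_ratio(s, c)[keep], striatum_tac.activity[keep] / cerebellum_tac.activity[keep]
        )

    def test_suvr_trivial_ratios(self, sched):
        one = compute_suv(TimeActivityCurve(sched, np.ones(sched.n_frames)), self.META)
        two = compute_suv(TimeActivityCurve(sched, np.full(sched.n_frames, 2.0)), self.META)
        np.testing.assert_allclose(suv_ratio(one, one), 1.0)
        np.testing.assert_allclose(suv_ratio(two, one), 2.0)

    def test_zero_reference_flagged_not_divided(self, sched):
        act = np.ones(sched.n_frames)
        act[0] = 0.0
        ref = compute_suv(TimeActivityCurve(sched, act), self.META)
        tgt = compute_suv(TimeActivityCurve(sched, np.ones(sched.n_frames)), self.META)
        with pytest.warns(RuntimeWarning):
            out = suv_ratio(tgt, ref)
        assert np.isnan(out[0]) and np.all(np.isfinite(out[1:]))


class TestPseudoEquilibrium:
    def test_constant_suvr_returns_whole_scan(self, sched):
        window = find_pseudo_equilibrium(np.ones(sched.n_frames), sched, 0.001)
        assert window == (0.0, 7200.0)

    def test_steep_ramp_returns_none(self, sched):
        suvr = 0.01 * sched.mid_times / 60.0  # slope 0.01/min everywhere
        assert find_pseudo_equilibrium(suvr, sched, 0.001) is None

    def test_ramp_then_flat_detects_the_plateau(self, sched):
        knee = 3000.0
        suvr = np.minimum(sched.mid_times, knee) / 1000.0
        start, end = find_pseudo_equilibrium(suvr, sched, 0.005)
        assert start >= knee  # plateau frames only
        assert end == sched.total_duration

    def test_simulated_suvr_approaches_equilibrium_late(
        self, striatum_tac, cerebellum_tac, sched
    ):
        # a nearly-trapped tracer approaches pseudo-equilibrium only loosely:
        # the SUVr slope must peak mid-scan and then decay monotonically, and
        # the relative slope in the final frames must be small (~<1%/min)
        suvr = striatum_tac.activity[1:] / cerebellum_tac.activity[1:]
        sub = FrameSchedule(sched.frame_starts[1:], sched.frame_durations[1:])
        slope = np.gradient(suvr, sub.mid_times / 60.0)
        peak = int(np.argmax(slope))
        assert 600.0 < sub.mid_times[peak] < 3600.0
        assert np.all(np.diff(slope[peak:]) < 0)
        assert slope[-1] / suvr[-1] < 0.01  # per-minute relative slope
        # and the detector, at a tolerance matching that relative slope,
        # reports a window extending to the end of the scan
        window = find_pseudo_equilibrium(suvr, sub, slope_tol_per_min=0.025)
        assert window is not None and window[1] == sched.total_duration
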