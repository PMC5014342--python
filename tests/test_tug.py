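import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import solegait as sg
from solegait.errors import (
    InsufficientStepsError,
    SegmentationError,
    UndefinedResultError,
)
from solegait.synthetic import GRAVITY
from solegait.tug import GaitParams, StepEvents, TUGPhases


def _phases(start=0.0, stand_end=2.0, turn_start=6.0, turn_end=7.0,
            walkback_end=11.0, end=12.0):
    return TUGPhases(start, stand_end, turn_start, turn_end, walkback_end, end)


class TestSegmentation:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_boundaries_within_quarter_second_of_ground_truth(self, seed):
        rec, gt = sg.simulate_tug(sg.healthy_profile(), seed=seed)
        ph = sg.segment_tug(rec)
        for attr in ("t_start", "t_stand_end", "t_turn_start", "t_turn_end",
                     "t_walkback_end", "t_end"):
            assert abs(getattr(ph, attr) - getattr(gt.phases, attr)) <= 0.25, attr

    def test_healthy_profile_trial_under_ten_seconds(self):
        rec, _ = sg.simulate_tug(sg.healthy_profile(), seed=4)
        ph = sg.segment_tug(rec)
        assert ph.tug_time < 10.0
        assert sg.categorize_tug(ph) == "normal"

    def test_zero_fsr_raises_segmentation_error(self):
        n = 500
        rec = sg.Recording(
            sample_rate=100.0, t=np.arange(n) / 100.0,
            accel_x=np.zeros(n), accel_y=np.zeros(n),
            accel_z=np.full(n, GRAVITY),
            fsr={"heel": np.zeros(n)},
        )
        with pytest.raises(SegmentationError):
            sg.segment_tug(rec)


class TestDetectSteps:
    def test_exact_count_on_noise_free_trial(self):
        g = sg.GaitProfile(n_strides=8, cadence_cv_nominal=0.0,
                           stride_cv_nominal=0.0)
        rec, gt = sg.simulate_tug(g, seed=0)
        ph = sg.segment_tug(rec)
        steps = sg.detect_steps(rec, ph)
        assert len(steps) == len(gt.step_times) == 17
        assert steps.source == "accel"

    def test_flat_signal_insufficient_steps(self):
        n = 1300
        rec = sg.Recording(
            sample_rate=100.0, t=np.arange(n) / 100.0,
            accel_x=np.zeros(n), accel_y=np.zeros(n),
            accel_z=np.full(n, GRAVITY),
            fsr={"heel": np.full(n, 50.0)},
        )
        with pytest.raises(InsufficientStepsError):
            sg.detect_steps(rec, _phases())

    def test_corrupted_accel_falls_back_to_fsr(self):
        rec, gt = sg.simulate_tug(sg.GaitProfile(n_strides=8), seed=2)
        ph = sg.segment_tug(rec)
        clean = sg.detect_steps(rec, ph)
        # wipe the acceleration bursts of every other step
        for st in gt.step_times[::2]:
            sel = (rec.t >= st - 0.15) & (rec.t <= st + 0.25)
            rec.accel_z[sel] = GRAVITY
        steps = sg.detect_steps(rec, ph)
        assert steps.source == "fsr"
        assert len(steps) == len(clean)  # FSR bursts are intact

    def test_step_times_strictly_increasing(self):
        rec, _ = sg.simulate_tug(sg.healthy_profile(), seed=6)
        ph = sg.segment_tug(rec)
        steps = sg.detect_steps(rec, ph)
        assert np.all(np.diff(steps.times) > 0)


class TestStrideLength:
    def test_unit_rectified_mean_gives_098(self):
        seg = np.tile([1.0, -1.0], 50)  # mean 0, |a| = 1
        assert sg.stride_length(seg) == pytest.approx(0.98)

    def test_rectified_mean_eight_gives_196(self):
        seg = np.tile([8.0, -8.0], 50)
        assert sg.stride_length(seg) == pytest.approx(0.98 * 2.0)

    def test_zero_signal_zero_length(self):
        assert sg.stride_length(np.zeros(20)) == 0.0

    def test_constant_offset_removed(self):
        seg = np.tile([1.0, -1.0], 50) + 9.81
        assert sg.stride_length(seg) == pytest.approx(0.98)


def _periodic_recording(step_times, rate=100.0, amp=3.0, tail=2.0):
    n = int((step_times[-1] + tail) * rate)
    t = np.arange(n) / rate
    az = np.full(n, GRAVITY)
    for st in step_times:
        sel = (t >= st) & (t < st + 0.3)
        az[sel] += amp * np.sin(2 * np.pi * (t[sel] - st) / 0.3)
    return sg.Recording(
        sample_rate=rate, t=t,
        accel_x=np.zeros(n), accel_y=np.zeros(n), accel_z=az,
        fsr={"heel": np.full(n, 50.0)},
    )


class TestGaitParams:
    def test_periodic_steps_constant_cadence(self):
        times = 2.0 + 0.5 * np.arange(13)
        rec = _periodic_recording(times)
        phases = TUGPhases(0.5, times[0], 4.70, 4.80, times[-1], times[-1] + 1)
        gp = sg.gait_params(StepEvents(times, "accel"), rec, phases)
        kept = gp.inst_cadence
        np.testing.assert_allclose(kept, 120.0, rtol=1e-9)

    def test_cadence_recovered_from_generator(self):
        g = sg.GaitProfile(n_strides=10, cadence_mean=100.0,
                           cadence_cv_nominal=0.0, stride_cv_nominal=0.0)
        rec, _ = sg.simulate_tug(g, seed=0)
        ph = sg.segment_tug(rec)
        gp = sg.gait_params(sg.detect_steps(rec, ph), rec, ph)
        assert gp.cadence_mean == pytest.approx(100.0, rel=0.01)

    def test_speed_is_accumulated_stride_length_over_walking_time(self):
        times = 2.0 + 0.5 * np.arange(13)
        rec = _periodic_recording(times)
        phases = TUGPhases(0.5, times[0], 4.70, 4.80, times[-1], times[-1] + 1)
        gp = sg.gait_params(StepEvents(times, "accel"), rec, phases)
        expected = np.sum(gp.stride_lengths) / (times[-1] - times[0])
        assert gp.speed == pytest.approx(expected)

    def test_too_few_steps_rejected(self):
        rec = _periodic_recording(np.array([2.0, 2.5]))
        with pytest.raises(InsufficientStepsError):
            sg.gait_params(StepEvents(np.array([2.0, 2.5]), "accel"), rec,
                           _phases())


class TestCV:
    def test_constant_series_zero(self):
        assert sg.coefficient_of_variation(np.full(5, 3.3)) == 0.0

    def test_hand_computed_example(self):
        assert sg.coefficient_of_variation(np.array([2.0, 4.0, 6.0])) == \
            pytest.approx(50.0)

    @pytest.mark.parametrize("k", [0.1, 2.0, 17.0])
    def test_scale_invariance(self, k):
        x = np.array([1.0, 1.2, 0.9, 1.1])
        assert sg.coefficient_of_variation(k * x) == \
            pytest.approx(sg.coefficient_of_variation(x))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        xs=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=25),
        k=st.floats(0.01, 50.0),
    )
    def test_scale_invariance_property(self, xs, k):
        x = np.array(xs)
        assert sg.coefficient_of_variation(k * x) == pytest.approx(
            sg.coefficient_of_variation(x), rel=1e-9, abs=1e-9
        )

    def test_matches_two_pass_moment_oracle(self):
        rng = np.random.default_rng(8)
        x = 5.0 + rng.random(100)
        cv = sg.coefficient_of_variation(x)
        # brute-force two-pass computation
        m = sum(x) / len(x)
        var = sum((v - m) ** 2 for v in x) / (len(x) - 1)
        oracle = 100.0 * var**0.5 / m
        assert abs(cv - oracle) <= 1e-12 * oracle

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedResultError):
            sg.coefficient_of_variation(np.array([-1.0, 1.0]))


def _gp(cv_cad, cv_sl, speed):
    """GaitParams whose series carry exactly the requested CVs."""
    # two-point series [m(1-d), m(1+d)] has sample CV = 100*d*sqrt(2)
    m = 100.0
    cad = np.array([m * (1 - cv_cad / 100 / np.sqrt(2)),
                    m * (1 + cv_cad / 100 / np.sqrt(2))])
    sl = np.array([1 - cv_sl / 100 / np.sqrt(2), 1 + cv_sl / 100 / np.sqrt(2)])
    return GaitParams(cadence_mean=m, inst_cadence=cad, stride_lengths=sl,
                      speed=speed)


class TestRisk:
    def test_regular_gait_zero_risk(self):
        r = sg.risk_of_falling(_gp(0.0, 0.0, 1.0))
        assert r.risk == 0.0

    def test_equation_with_unit_speed(self):
        r = sg.risk_of_falling(_gp(10.0, 10.0, 1.0))
        assert r.cv_cadence == pytest.approx(10.0)
        assert r.cv_stride == pytest.approx(10.0)
        assert r.risk == pytest.approx(20.0)

    def test_doubling_speed_halves_risk(self):
        r1 = sg.risk_of_falling(_gp(10.0, 10.0, 1.0))
        r2 = sg.risk_of_falling(_gp(10.0, 10.0, 2.0))
        assert r2.risk == pytest.approx(r1.risk / 2)

    def test_monotone_in_cv_and_speed(self):
        grid_cv = [2.0, 5.0, 8.0, 11.0, 14.0]
        speeds = [0.5, 1.0, 1.5]
        for speed in speeds:
            for cv_s in grid_cv:
                risks = [sg.risk_of_falling(_gp(c, cv_s, speed)).risk
                         for c in grid_cv]
                assert np.all(np.diff(risks) > 0)
            for cv_c in grid_cv:
                risks = [sg.risk_of_falling(_gp(cv_c, s, speed)).risk
                         for s in grid_cv]
                assert np.all(np.diff(risks) > 0)
        for cv in grid_cv:
            risks = [sg.risk_of_falling(_gp(cv, cv, s)).risk for s in speeds]
            assert np.all(np.diff(risks) < 0)

    def test_zero_speed_undefined(self):
        with pytest.raises(UndefinedResultError):
            sg.risk_of_falling(_gp(5.0, 5.0, 0.0))


class TestCategory:
    @pytest.mark.parametrize("tug_time,expected", [
        (8.0, "normal"),
        (17.0, "increased_risk"),
        (10.0, "intermediate"),
        (16.0, "intermediate"),
        (12.0, "intermediate"),
    ])
    def test_thresholds(self, tug_time, expected):
        ph = TUGPhases(0.0, 1.0, 2.0, 3.0, tug_time - 0.5, tug_time)
        assert sg.categorize_tug(ph) == expected
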