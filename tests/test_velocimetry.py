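import io

import numpy as np
import pytest

from finprop import velocimetry as vm
from finprop.synthetic import SyntheticTrackSpec, gen_track


class TestLoadTracks:
    def test_plain_three_row_fixture(self):
        csv = io.StringIO("frame,x,y,confidence\n0,1.0,2.0,0.99\n1,1.5,2.0,0.98\n2,2.0,2.1,0.97\n")
        tr = vm.load_tracks(csv)
        assert len(tr) == 3
        assert tr.x[1] == 1.5

    def test_pose_export_dialect(self):
        csv = io.StringIO(
            "scorer,net,net,net,net,net,net\n"
            "bodyparts,mouth,mouth,mouth,fin_tip,fin_tip,fin_tip\n"
            "coords,x,y,likelihood,x,y,likelihood\n"
            "0,10.0,5.0,0.99,20.0,6.0,0.95\n"
            "1,11.0,5.1,0.98,21.0,5.5,0.94\n")
        tr = vm.load_tracks(csv, dialect="pose_export", keypoint="fin_tip")
        assert tr.keypoint == "fin_tip"
        assert tr.x[0] == 20.0
        assert tr.confidence[1] == 0.94

    def test_missing_columns_named_in_error(self):
        csv = io.StringIO("frame,x\n0,1.0\n")
        with pytest.raises(vm.TrackFormatError, match="y"):
            vm.load_tracks(csv)

    def test_non_monotonic_frames_rejected(self):
        csv = io.StringIO("frame,x,y,confidence\n0,1,1,1\n2,1,1,1\n1,1,1,1\n")
        with pytest.raises(vm.TrackFormatError, match="increasing"):
            vm.load_tracks(csv)

    def test_low_confidence_rows_flagged(self):
        n = 30
        tr = vm.TrackSeries(frames=np.arange(n), x=np.arange(n, dtype=float),
                            y=np.zeros(n), confidence=np.full(n, 0.2))
        with pytest.raises(vm.InsufficientDataError):
            vm.estimate_speed(tr, conf_threshold=0.9)

    def test_round_trip(self):
        track, _ = gen_track(SyntheticTrackSpec(seed=7))
        buf = io.StringIO()
        vm.write_tracks(track, buf)
        buf.seek(0)
        back = vm.load_tracks(buf)
        assert np.allclose(back.x, track.x)
        assert np.array_equal(back.frames, track.frames)


class TestEstimateSpeed:
    def test_noiseless_constant_velocity_exact(self):
        track, _ = gen_track(SyntheticTrackSpec(
            profile="constant_velocity", v=1.0, noise_px=0.0, duration=1.0))
        est = vm.estimate_speed(track)
        interior = est.speed[8:-8]
        assert np.allclose(interior, 1.0, atol=1e-9)

    def test_constant_acceleration_slope_recovered(self):
        track, truth = gen_track(SyntheticTrackSpec(
            profile="constant_acceleration", a=0.64, noise_px=0.0,
            duration=1.14))
        est = vm.estimate_speed(track)
        slope = np.polyfit(est.times[8:-8], est.speed[8:-8], 1)[0]
        assert slope == pytest.approx(0.64, rel=0.01)

    def test_noisy_constant_velocity_within_five_percent(self):
        track, _ = gen_track(SyntheticTrackSpec(
            profile="constant_velocity", v=1.0, noise_px=1.0,
            duration=2.0, seed=42))
        est = vm.estimate_speed(track)
        assert np.mean(est.speed[10:-10]) == pytest.approx(1.0, rel=0.05)

    def test_translation_invariance_and_scale_linearity(self):
        track, _ = gen_track(SyntheticTrackSpec(
            profile="constant_velocity", v=0.8, noise_px=0.0, duration=1.0))
        est0 = vm.estimate_speed(track)
        track.x = track.x + 500.0
        track.y = track.y + 120.0
        assert np.allclose(vm.estimate_speed(track).speed, est0.speed)
        track.scale *= 2.0
        assert np.allclose(vm.estimate_speed(track).speed, 2.0 * est0.speed)

    def test_integrating_speed_recovers_displacement(self):
        track, truth = gen_track(SyntheticTrackSpec(
            profile="constant_acceleration", a=0.5, noise_px=0.0, duration=2.0))
        est = vm.estimate_speed(track)
        displacement = np.trapezoid(est.speed, est.times)
        exact = 0.5 * 0.5 * est.times[-1] ** 2   # BL over the sampled window
        assert displacement == pytest.approx(exact, rel=0.01)


class TestFinFrequency:
    @pytest.mark.parametrize("f_true", [14.0, 29.0])
    def test_sinusoid_recovered_within_crossing_quantum(self, f_true):
        fps, dur = 60.0, 1.0
        t = np.arange(int(fps * dur)) / fps
        tr = vm.TrackSeries(frames=np.arange(len(t)),
                            x=np.zeros(len(t)),
                            y=10.0 * np.sin(2 * np.pi * f_true * t),
                            confidence=np.ones(len(t)), fps=fps)
        quantum = 1.0 / (2.0 * (t[-1] - t[0]))
        assert vm.fin_frequency(tr) == pytest.approx(f_true, abs=quantum + 1e-9)

    def test_constant_signal_rejected(self):
        tr = vm.TrackSeries(frames=np.arange(60), x=np.zeros(60),
                            y=np.full(60, 3.3), confidence=np.ones(60))
        with pytest.raises(vm.InsufficientDataError):
            vm.fin_frequency(tr)

    def test_periodogram_agrees_with_crossings(self):
        fps = 60.0
        t = np.arange(120) / fps
        tr = vm.TrackSeries(frames=np.arange(len(t)), x=np.zeros(len(t)),
                            y=np.sin(2 * np.pi * 10.0 * t),
                            confidence=np.ones(len(t)), fps=fps)
        assert vm.fin_frequency(tr, "periodogram") == pytest.approx(10.0, abs=0.5)


class TestCorrelateFU:
    def test_exact_line(self):
        f = np.array([10.0, 15.0, 20.0, 29.0])
        slope, intercept, r = vm.correlate_f_u(f, 0.1 * f)
        assert slope == pytest.approx(0.1)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        f = np.array([10.0, 20.0, 30.0])
        _, _, r = vm.correlate_f_u(f, -0.05 * f + 3.0)
        assert r < 0

    def test_noisy_slope_within_standard_error(self, rng):
        f = rng.uniform(8, 32, 40)
        u = 0.095 * f + rng.normal(0, 0.15, 40)
        slope, _, _ = vm.correlate_f_u(f, u)
        from scipy.stats import linregress
        se = linregress(f, u).stderr
        assert abs(slope - 0.095) <= 2 * se

    def test_degenerate_f_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            vm.correlate_f_u([10.0, 10.0, 10.0], [1.0, 2.0, 3.0])
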