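"""Envelopes, onset detection, fit metrics, wave-speed and spread estimators."""

import numpy as np
import pytest

from epifield.analysis import (
    OnsetResult,
    VelocitySweep,
    calibrate_gamma11,
    detect_onsets,
    estimate_data_velocity,
    estimate_speed_from_traces,
    fit_metrics,
    flattened_spectrogram,
    signal_envelope,
)
from epifield.forward import SensorSignals

FS = 256.0


def _signals(arr, fs=FS):
    arr = np.asarray(arr, float)
    names = [f"c{i+2}-c{i+1}" for i in range(arr.shape[1])]
    return SensorSignals(arr, names, fs, "bipolar")


def _ramp_channel(t, t0=10.0, t1=20.0, f=8.0):
    """Amplitude ramps linearly from 0 (t0) to 1 (t1), then stays."""
    amp = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return amp * np.sin(2 * np.pi * f * t)


class TestEnvelope:
    def test_zero_signal_zero_envelope(self):
        env = signal_envelope(np.zeros(4096), FS)
        assert np.all(env == 0)

    def test_stationary_sine_envelope_is_mean_rectified(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        env = signal_envelope(x, FS)
        late = env[int(20 * FS): int(40 * FS)]
        assert late.mean() == pytest.approx(2 / np.pi, rel=0.05)

    def test_dc_offset_removed(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        e0 = signal_envelope(x, FS)
        e1 = signal_envelope(x + 5.0, FS)
        mid = slice(int(10 * FS), int(50 * FS))
        assert np.max(np.abs(e0[mid] - e1[mid])) / e0[mid].mean() < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            signal_envelope(np.zeros(100), fs=1.0)


class TestDetectOnsets:
    def test_linear_ramp_crosses_at_20pct(self):
        t = np.arange(int(40 * FS)) / FS
        sig = _signals(_ramp_channel(t)[:, None])
        res = detect_onsets(sig)
        # 20% of max amplitude reached at t = 12 s on the 10->20 s ramp;
        # single channel is shifted to zero, so compare raw crossing index
        env = res.envelopes[:, 0]
        cross = np.flatnonzero(env >= 0.2 * env.max())[0] / FS
        assert cross == pytest.approx(12.0, abs=0.5)

    def test_identical_channels_share_zero_onset(self):
        t = np.arange(int(40 * FS)) / FS
        ch = _ramp_channel(t)
        res = detect_onsets(_signals(np.column_stack([ch, ch])))
        assert res.onset_times == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_shift_equivariance(self):
        t = np.arange(int(40 * FS)) / FS
        a = _ramp_channel(t, t0=10.0, t1=20.0)
        b = _ramp_channel(t, t0=11.0, t1=21.0)
        res = detect_onsets(_signals(np.column_stack([a, b])))
        assert res.onset_times[1] - res.onset_times[0] == pytest.approx(1.0, abs=0.05)

    def test_amplitude_rescaling_invariance(self):
        t = np.arange(int(40 * FS)) / FS
        x = np.column_stack([_ramp_channel(t), _ramp_channel(t, t0=12.0, t1=22.0)])
        r1 = detect_onsets(_signals(x))
        r2 = detect_onsets(_signals(1000.0 * x))
        assert r1.onset_times == pytest.approx(r2.onset_times, abs=1e-9)

    def test_silent_channel_flagged_not_zeroed(self):
        t = np.arange(int(40 * FS)) / FS
        x = np.column_stack([_ramp_channel(t), np.zeros_like(t)])
        res = detect_onsets(_signals(x))
        assert res.detected[0]
        assert not res.detected[1]
        assert np.isnan(res.onset_times[1])


class TestFitMetrics:
    def test_identical_inputs(self):
        m = fit_metrics([0, 1, 2], [0, 1, 2], [1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert (m.rmse, m.mae, m.rho) == (0.0, 0.0, pytest.approx(1.0))

    def test_arithmetic_example(self):
        m = fit_metrics([0, 1, 2], [0, 2, 4], [1, 2, 3], [2, 4, 6])
        assert m.rmse == pytest.approx(np.sqrt(5 / 3), rel=1e-12)
        assert m.mae == pytest.approx(1.0, rel=1e-12)
        assert m.rho == pytest.approx(1.0)

    def test_argument_order_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=8)
        e, f = rng.random(8), rng.random(8)
        m1 = fit_metrics(a, b, e, f)
        m2 = fit_metrics(b, a, f, e)
        assert m1.rmse == pytest.approx(m2.rmse)
        assert m1.mae == pytest.approx(m2.mae)
        assert m1.rho == pytest.approx(m2.rho)

    def test_rmse_bounds_mae(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(size=10)
        m = fit_metrics(a, b, np.arange(10.0), np.arange(10.0))
        assert m.rmse >= m.mae >= 0

    def test_constant_envelope_rho_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            m = fit_metrics([0, 1], [0, 1], [2.0, 2.0], [1.0, 3.0])
        assert np.isnan(m.rho)


class TestWaveSpeed:
    GRID = np.linspace(50.0, 1000.0, 200)

    def _plane_wave(self, speed, fs=256.0, n_pts=30, dur=1.0, f=8.0, noise=0.0, seed=0):
        d = np.linspace(0.0, 29.0, n_pts)
        t = np.arange(int(dur * fs)) / fs
        rng = np.random.default_rng(seed)
        traces = np.sin(2 * np.pi * f * (t[None, :] - d[:, None] / speed))
        traces += noise * rng.standard_normal(traces.shape)
        return traces, d

    @pytest.mark.parametrize("speed", [100.0, 300.0, 600.0, 900.0])
    def test_recovers_plane_wave_speed(self, speed):
        traces, d = self._plane_wave(speed)
        est = estimate_speed_from_traces(traces, d, 256.0, self.GRID)
        step = self.GRID[1] - self.GRID[0]
        assert abs(est.speed - speed) <= step + 1e-9
        assert not est.low_confidence

    def test_synchronous_field_saturates_at_grid_edge(self):
        traces, d = self._plane_wave(1e9)
        est = estimate_speed_from_traces(traces, d, 256.0, self.GRID)
        assert est.speed == self.GRID[-1]
        assert est.at_grid_edge

    def test_independent_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(7)
        traces = rng.standard_normal((30, 256))
        d = np.linspace(0, 29, 30)
        est = estimate_speed_from_traces(traces, d, 256.0, self.GRID)
        assert est.best_correlation < 0.3
        assert est.low_confidence


class TestCalibration:
    def _sweep(self):
        return VelocitySweep(
            np.array([0.5, 1.0, 1.5, 2.0]), np.array([2.0, 6.0, 11.0, 14.0])
        )

    def test_exact_sample_returned(self):
        assert calibrate_gamma11(self._sweep(), 6.0) == pytest.approx(1.0)

    def test_interpolation_between_samples(self):
        g = calibrate_gamma11(self._sweep(), 8.5)
        assert 1.0 < g < 1.5

    def test_target_outside_range_rejected(self):
        with pytest.raises(ValueError, match="extend"):
            calibrate_gamma11(self._sweep(), 20.0)

    def test_nan_velocities_ignored(self):
        sweep = VelocitySweep(
            np.array([0.2, 0.5, 1.0]), np.array([np.nan, 2.0, 6.0])
        )
        assert calibrate_gamma11(sweep, 4.0) == pytest.approx(0.75)


class TestDataVelocity:
    def _onsets(self, times):
        times = np.asarray(times, float)
        return OnsetResult(
            times, np.isfinite(times), np.zeros((1, len(times))),
            np.zeros(len(times)), [f"b{i}" for i in range(len(times))], 256.0
        )

    def test_arithmetic(self, flat_coarse):
        surface, electrode = flat_coarse
        v = estimate_data_velocity(self._onsets([0, 1, 2, 3, 4, 3.9, 3.95, 4.0]),
                                   surface, electrode)
        # geodesic between the vertices nearest the end contacts is 28 mm
        # up to grid snapping of the contact feet
        assert v == pytest.approx(28.0 / 4.0, rel=0.05)

    def test_reversed_onsets_rejected(self, flat_coarse):
        surface, electrode = flat_coarse
        with pytest.raises(ValueError):
            estimate_data_velocity(self._onsets([4, 3, 2, 1, 0, 0, 0, 0]),
                                   surface, electrode)

    def test_sine_geodesic_not_shorter_than_flat(self):
        from epifield.mesh import geodesic_distances
        from epifield.surrogates import (SurrogateSpec, make_sine_surrogate,
                                         nearest_vertex)

        surf, e = make_sine_surrogate(SurrogateSpec(kind="sine", target_edge_length=1.0))
        a = nearest_vertex(surf, e.contact_positions[0])
        b = nearest_vertex(surf, e.contact_positions[-1])
        d = geodesic_distances(surf, a).distances[b]
        assert d >= 28.0  # folded path at least the straight span


class TestSpectrogram:
    def test_pure_sine_peak_at_8hz(self):
        t = np.arange(int(20 * FS)) / FS
        f, tt, p = flattened_spectrogram(np.sin(2 * np.pi * 8.0 * t), FS)
        peak = f[np.argmax(p.mean(axis=1))]
        assert peak == pytest.approx(8.0, abs=1.0)

    def test_one_over_f_noise_flattens(self):
        rng = np.random.default_rng(11)
        n = int(64 * FS)
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1 / FS)
        spec[1:] /= np.sqrt(freqs[1:])
        pink = np.fft.irfft(spec, n)
        f, tt, p = flattened_spectrogram(pink, FS)
        mean_p = p.mean(axis=1)
        band = (f > 2) & (f < 100)
        slope = np.polyfit(np.log(f[band]), np.log(mean_p[band]), 1)[0]
        assert abs(slope) < 0.35

    def test_zero_signal_zero_map(self):
        f, tt, p = flattened_spectrogram(np.zeros(int(4 * FS)), FS)
        assert np.all(p == 0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            flattened_spectrogram(np.zeros(100), FS, window=1.0)


class TestMetricProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    pair_lists = st.lists(
        st.tuples(
            st.floats(-5, 5, allow_nan=False, allow_infinity=False),
            st.floats(-5, 5, allow_nan=False, allow_infinity=False),
        ),
        min_size=2,
        max_size=12,
    )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(pair_lists)
    def test_rmse_between_mae_and_max_error(self, pairs):
        a, b = map(np.asarray, zip(*pairs))
        env = np.arange(float(len(a)))
        m = fit_metrics(a, b, env, env)
        err = np.abs(a - b)
        assert m.mae - 1e-12 <= m.rmse <= err.max() + 1e-12
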