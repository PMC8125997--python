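"""RC response simulation: ODE vs analytic convolution, portraits, PSD."""

import numpy as np
import pytest

from ringeit.circuit import (
    RCSeriesModel,
    convolution_solution,
    phase_portrait,
    postprocess_signal,
    simulate_response,
    tile_periods,
    transfer_function,
)
from ringeit.waveforms import SampledWaveform, WaveformSpec, sample_waveform

# bench configuration of the waveform comparison experiment
BENCH = RCSeriesModel(resistance=218.6, capacitance=1e-6)
BENCH_F = 11430.0


class TestTransferFunction:
    def test_pole_location(self):
        tf = transfer_function(RCSeriesModel(20.0, 1e-6))
        assert tf.poles[0] == pytest.approx(-50000.0)

    @pytest.mark.parametrize("R,C", [(1.0, 1e-9), (218.6, 1e-6), (1024.0, 1e-3)])
    def test_stability_and_dc_gain(self, R, C):
        tf = transfer_function(RCSeriesModel(R, C))
        assert tf.dc_gain == 1.0
        assert np.isreal(tf.poles[0]) and tf.poles[0] < 0

    def test_impulse_response(self):
        tf = transfer_function(RCSeriesModel(100.0, 1e-6))
        tau = 1e-4
        t = np.array([-1.0, 0.0, tau])
        h = tf.impulse_response(t)
        assert h[0] == 0.0
        assert h[1] == pytest.approx(1.0 / tau)
        assert h[2] == pytest.approx(np.exp(-1.0) / tau)


class TestConvolution:
    def test_zero_input_decays_from_y0(self):
        model = RCSeriesModel(100.0, 1e-6)
        t = np.linspace(0.0, 5 * model.tau, 2000)
        y = convolution_solution(model, (t, np.zeros_like(t)), y0=2.0)
        assert np.allclose(y, 2.0 * np.exp(-t / model.tau), rtol=1e-9, atol=1e-12)

    def test_step_response_closed_form(self):
        model = RCSeriesModel(100.0, 1e-6)
        t = np.linspace(0.0, 5 * model.tau, 2000)
        y = convolution_solution(model, (t, np.full_like(t, 1.5)), y0=0.0)
        assert np.allclose(y, 1.5 * (1.0 - np.exp(-t / model.tau)), rtol=1e-9, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            convolution_solution(RCSeriesModel(1.0, 1.0), (np.array([]), np.array([])))

    def test_nonuniform_grid_matches_uniform(self):
        # the scalar recurrence and the filter fast path must agree
        model = RCSeriesModel(218.6, 1e-6)
        t = np.linspace(0.0, 3 * model.tau, 1501)
        u = np.sin(2 * np.pi * t / model.tau)
        y_uni = convolution_solution(model, (t, u))
        t2 = np.concatenate([t, [t[-1] + 1e-3 * model.tau]])
        u2 = np.concatenate([u, [u[-1]]])
        y_non = convolution_solution(model, (t2, u2))
        assert np.allclose(y_uni, y_non[:-1], rtol=1e-12, atol=1e-14)


class TestSimulateResponse:
    def test_dc_input_reaches_unit_gain(self):
        model = RCSeriesModel(100.0, 1e-6)
        sw = SampledWaveform(np.linspace(0, 10 * model.tau, 64), np.full(64, 2.0))
        sim = simulate_response(model, sw, n_periods=1, points_per_period=256)
        assert sim.y[-1] == pytest.approx(2.0, rel=1e-4)

    def test_sine_steady_state_gain(self):
        """First-order amplitude ratio 1/sqrt(1+(wRC)^2) within 0.1%."""
        model = BENCH
        spec = WaveformSpec("F", frequency=BENCH_F)
        sim = simulate_response(model, spec, n_periods=30, points_per_period=256)
        T = 1.0 / BENCH_F
        last = sim.times >= sim.times[-1] - 4 * T
        # least-squares quadrature fit of the steady-state sine amplitude
        t, y = sim.times[last], sim.y[last]
        M = np.column_stack(
            [np.sin(2 * np.pi * BENCH_F * t), np.cos(2 * np.pi * BENCH_F * t), np.ones_like(t)]
        )
        cs, cc, _ = np.linalg.lstsq(M, y, rcond=None)[0]
        amp = np.hypot(cs, cc)
        w = 2 * np.pi * BENCH_F
        gain = 1.0 / np.sqrt(1.0 + (w * model.tau) ** 2)
        assert amp / 0.5 == pytest.approx(gain, rel=1e-3)

    @pytest.mark.parametrize("kind", "ABCDEF")
    def test_matches_convolution_oracle(self, kind):
        """Stiff ODE path and exact exponential integrator agree to 1e-6."""
        spec = WaveformSpec(kind, frequency=BENCH_F)
        sim = simulate_response(BENCH, spec, n_periods=3, points_per_period=512)
        sw = sample_waveform(spec, 8192, include_breaks=True)
        tt, vv = tile_periods(sw, 3)
        y = convolution_solution(BENCH, (tt, vv))
        yi = np.interp(sim.times, tt, y)
        rel_rms = np.sqrt(np.mean((sim.y - yi) ** 2) / np.mean(yi**2))
        assert rel_rms < 1e-6

    def test_exponential_pulse_matches_convolution(self):
        spec = WaveformSpec("EXP", frequency=BENCH_F, exp_factor=5.0)
        model = RCSeriesModel(20.0, 1e-6)
        sim = simulate_response(model, spec, n_periods=3, points_per_period=512)
        sw = sample_waveform(spec, 8192, include_breaks=True)
        tt, vv = tile_periods(sw, 3)
        y = convolution_solution(model, (tt, vv))
        yi = np.interp(sim.times, tt, y)
        rel_rms = np.sqrt(np.mean((sim.y - yi) ** 2) / np.mean(yi**2))
        assert rel_rms < 1e-6

    def test_linearity_of_response(self):
        model = BENCH
        s1 = sample_waveform(WaveformSpec("F", frequency=BENCH_F), 2048)
        s2 = sample_waveform(WaveformSpec("D", frequency=BENCH_F), 2048)
        t, u1 = tile_periods(s1, 2)
        _, u2 = tile_periods(s2, 2)
        ya = convolution_solution(model, (t, 2.0 * u1 + 3.0 * u2))
        yb = 2.0 * convolution_solution(model, (t, u1)) + 3.0 * convolution_solution(
            model, (t, u2)
        )
        assert np.allclose(ya, yb, rtol=1e-12, atol=1e-14)

    def test_current_satisfies_kvl(self):
        sim = simulate_response(BENCH, WaveformSpec("F", frequency=BENCH_F))
        assert np.allclose(sim.i, (sim.u - sim.y) / BENCH.resistance)


class TestPhasePortrait:
    def _sine_sim(self, n_periods=10):
        return simulate_response(
            BENCH, WaveformSpec("F", frequency=BENCH_F), n_periods=n_periods
        )

    def test_scaled_ranges(self):
        pp = phase_portrait(self._sine_sim(), scaled=True, period=1 / BENCH_F)
        for plane in pp.values():
            assert plane.min() == pytest.approx(0.0, abs=1e-12)
            assert plane.max() == pytest.approx(1.0, abs=1e-12)

    def test_sine_trajectory_is_elliptic(self):
        """Steady-state (u, y) loop of a sine drive is an ellipse."""
        pp = phase_portrait(self._sine_sim(), period=1 / BENCH_F)
        x, y = pp["uy"][:, 0], pp["uy"][:, 1]
        # algebraic conic fit: smallest singular vector of the design matrix
        D = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
        _, s, Vt = np.linalg.svd(D, full_matrices=False)
        residual = s[-1] / s[0]
        assert residual < 1e-4
        a, b, c = Vt[-1][:3]
        assert b * b - 4 * a * c < 0  # elliptic, not hyperbolic

    def test_dc_input_collapses_to_point(self):
        model = RCSeriesModel(100.0, 1e-6)
        sw = SampledWaveform(np.linspace(0, 20 * model.tau, 64), np.full(64, 1.0))
        sim = simulate_response(model, sw, n_periods=1, points_per_period=512)
        pp = phase_portrait(sim, period=10 * model.tau)
        spread = np.ptp(pp["uy"], axis=0)
        assert np.all(spread < 1e-6)

    def test_constant_variable_rejected_when_scaling(self):
        model = RCSeriesModel(100.0, 1e-6)
        sw = SampledWaveform(np.linspace(0, 20 * model.tau, 64), np.full(64, 1.0))
        sim = simulate_response(model, sw, n_periods=1, points_per_period=512)
        with pytest.raises(ValueError, match="u"):
            phase_portrait(sim, scaled=True)


class TestPostprocess:
    def test_psd_peak_at_fundamental(self):
        fs, f0 = 1e6, 11430.0
        t = np.arange(0, 0.02, 1 / fs)
        x = np.sin(2 * np.pi * f0 * t)
        _, (freqs, dens) = postprocess_signal(x, fs, cutoff=1e5, psd=True)
        assert abs(freqs[np.argmax(dens)] - f0) <= freqs[1] - freqs[0]

    def test_parseval_within_two_percent(self):
        rng = np.random.default_rng(7)
        fs = 1e6
        x = rng.normal(size=65536)
        _, (freqs, dens) = postprocess_signal(x, fs, cutoff=1e5, psd=True, nperseg=4096)
        power = np.trapezoid(dens, freqs)
        assert power == pytest.approx(np.var(x), rel=0.02)

    def test_lowpass_removes_noise_power(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=16384)
        filtered = postprocess_signal(x, fs=1e6, cutoff=1e5)
        assert np.var(filtered) < np.var(x)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            postprocess_signal(np.zeros(128), fs=1e5, cutoff=6e4)


class TestHarmonicContent:
    def test_non_sine_waveforms_have_stronger_second_harmonic(self):
        """Responses to A-E carry marked harmonics; the sine response F
        concentrates its power at the fundamental."""
        ratios = {}
        n_per, ppp, n_tail = 24, 512, 8
        for kind in "ABCDEF":
            spec = WaveformSpec(kind, frequency=BENCH_F)
            sw = sample_waveform(spec, ppp, include_breaks=False)
            tt, vv = tile_periods(sw, n_per)
            tu = np.linspace(0.0, n_per / BENCH_F, n_per * ppp, endpoint=False)
            y = convolution_solution(BENCH, (tu, np.interp(tu, tt, vv)))
            # analyze the final periods, well past the 5 RC transient
            tail = y[-n_tail * ppp :]
            spec_mag = np.abs(np.fft.rfft(tail - tail.mean()))
            ratios[kind] = spec_mag[2 * n_tail] / spec_mag[n_tail]
        for kind in "ABCDE":
            assert ratios[kind] > ratios["F"]
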