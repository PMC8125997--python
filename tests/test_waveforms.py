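"""Waveform definitions, energies, Fourier series and quantization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ringeit.waveforms import (
    FourierApprox,
    WaveformSpec,
    closed_form_energy,
    compose_waveform_B,
    dequantize,
    energy_composite_identity,
    eval_waveform,
    fourier_approx_exp,
    quantize,
    sample_waveform,
    waveform_energy,
)

# one-period energies at f = 1, printed to five significant digits
TABLE_ENERGIES = {
    "A": 9.8689e-2,
    "B": 2.8252e-1,
    "C": 3.0000e-1,
    "D": 3.3333e-1,
    "E": 3.3333e-1,
    "F": 3.7500e-1,
}


class TestEval:
    @pytest.mark.parametrize(
        "kind, t, expected",
        [
            ("F", 0.25, 1.0),  # sine peak at quarter period
            ("D", 0.5, 0.5),  # ramp mid-period
            ("A", 0.5, 1.0),  # exponential rise reaches 1 at mid-period
            ("C", 1e-12, 0.5),  # first parabolic branch starts at 1/2
            ("E", 0.25, 0.75),  # falling ramp
        ],
    )
    def test_pointwise_values(self, kind, t, expected):
        spec = WaveformSpec(kind, frequency=1.0)
        assert eval_waveform(spec, t) == pytest.approx(expected, abs=1e-9)

    def test_periodic_wrapping(self):
        spec = WaveformSpec("F", frequency=2.0)
        t = np.linspace(0.01, 0.49, 50)
        assert np.allclose(eval_waveform(spec, t), eval_waveform(spec, t + 3 * 0.5))

    def test_branch_boundary_belongs_to_first_branch(self):
        # waveform C jumps at mid-period; the boundary takes the left value
        spec = WaveformSpec("C", frequency=1.0)
        assert eval_waveform(spec, 0.5) == pytest.approx(1.0)
        assert eval_waveform(spec, 0.5 + 1e-9) == pytest.approx(0.0, abs=1e-8)

    def test_amplitude_scaling(self):
        a = eval_waveform(WaveformSpec("F", amplitude=3.0), 0.25)
        assert a == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "Z"},
            {"kind": "A", "frequency": 0.0},
            {"kind": "A", "amplitude": -1.0},
            {"kind": "EXP", "exp_factor": -2.0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        kwargs.setdefault("kind", "A")
        with pytest.raises(ValueError):
            WaveformSpec(**kwargs)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        kind=st.sampled_from("ABCDEF"),
        f=st.floats(0.1, 1e5),
        x=st.floats(0.0, 1.0, exclude_min=True),
    )
    def test_normalized_range(self, kind, f, x):
        """Every table waveform stays inside [0, 1] over the period."""
        spec = WaveformSpec(kind, frequency=f)
        v = eval_waveform(spec, x / f)
        assert -1e-9 <= v <= 1.0 + 1e-9


class TestEnergy:
    @pytest.mark.parametrize("kind", list(TABLE_ENERGIES))
    def test_energy_values_five_digits(self, kind):
        e = waveform_energy(WaveformSpec(kind, frequency=1.0))
        assert e == pytest.approx(TABLE_ENERGIES[kind], rel=1e-4)

    @pytest.mark.parametrize("kind", ["A", "C", "D", "E", "F"])
    def test_quadrature_matches_closed_form(self, kind):
        e_quad = waveform_energy(WaveformSpec(kind, frequency=1.0))
        assert e_quad == pytest.approx(closed_form_energy(kind, 1.0), rel=1e-9)

    @pytest.mark.parametrize("f", [0.5, 1.0, 2.0, 11430.0])
    @pytest.mark.parametrize("kind", ["A", "C", "D", "F"])
    def test_energy_scales_inversely_with_frequency(self, kind, f):
        e1 = waveform_energy(WaveformSpec(kind, frequency=1.0))
        ef = waveform_energy(WaveformSpec(kind, frequency=f))
        assert ef == pytest.approx(e1 / f, rel=1e-8)

    def test_energy_ordering(self):
        es = [waveform_energy(WaveformSpec(k)) for k in "ABCDEF"]
        assert es[0] < es[1] < es[2] < es[3] <= es[4] < es[5]
        assert es[3] == pytest.approx(es[4], rel=1e-9)  # both ramps: 1/(3f)

    def test_amplitude_scales_energy_quadratically(self):
        sw = sample_waveform(WaveformSpec("F", amplitude=3.0), 4096)
        e = waveform_energy(sw)
        assert e == pytest.approx(9.0 * 0.375, rel=1e-4)

    def test_ramp_energy_at_f2(self):
        # closed form 1/(3f) halves at f = 2
        assert waveform_energy(WaveformSpec("D", frequency=2.0)) == pytest.approx(
            1.0 / 6.0, rel=1e-9
        )


class TestCompositeB:
    def test_scaling_bounds(self):
        # 4097 samples put a node exactly on the mid-period kink where the
        # composite attains its maximum
        sw = compose_waveform_B(1.0, 4097)
        assert sw.values.min() == pytest.approx(0.0, abs=1e-6)
        assert sw.values.max() == pytest.approx(1.0, abs=1e-6)

    def test_energy_five_digits(self):
        e = waveform_energy(WaveformSpec("B", frequency=1.0))
        assert e == pytest.approx(2.8252e-1, rel=1e-4)

    def test_energy_identity_cross_check(self):
        """Direct quadrature of u_B^2 agrees with the expanded-sum form."""
        direct = waveform_energy(WaveformSpec("B", frequency=1.0))
        expanded = energy_composite_identity(1.0)
        assert direct == pytest.approx(expanded, rel=1e-8)

    def test_minimum_sample_count_enforced(self):
        with pytest.raises(ValueError):
            compose_waveform_B(1.0, 8)


class TestFourierExp:
    def test_zero_terms_is_period_mean(self):
        A, B, f = 1.0, 5.0, 1.0
        fa = fourier_approx_exp(A, B, f, 0)
        mean_quad, _ = quad(
            lambda t: A * math.exp(-B * abs(2 * f * t - 1)), 0.0, 1.0, epsabs=1e-12
        )
        assert fa.n_terms == 0
        assert fa(0.123) == pytest.approx(mean_quad, rel=1e-10)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_coefficients_match_quadrature(self, n):
        """Analytic cosine amplitudes reproduce the Fourier integrals."""
        A, B, f = 2.0, 5.0, 3.0
        fa = fourier_approx_exp(A, B, f, 5)
        val, _ = quad(
            lambda t: A
            * math.exp(-B * abs(2 * f * t - 1))
            * math.cos(2 * math.pi * f * n * t),
            0.0,
            1.0 / f,
            epsabs=1e-14,
            limit=200,
        )
        assert fa.cosine_coefficients[n - 1] == pytest.approx(2.0 * f * val, rel=1e-8)

    def test_truncation_error_decreases(self):
        A, B, f = 1.0, 5.0, 1.0
        t = np.linspace(0.0, 1.0, 4001)
        truth = A * np.exp(-B * np.abs(2 * f * t - 1))
        errs = []
        for k in (10, 50, 200):
            approx = fourier_approx_exp(A, B, f, k)(t)
            errs.append(np.sqrt(np.trapezoid((approx - truth) ** 2, t)))
        assert errs[0] > errs[1] > errs[2]


class TestQuantize:
    def test_constant_wave_single_code(self):
        sw = sample_waveform(WaveformSpec("F"), 256)
        const = type(sw)(sw.sample_times, np.full_like(sw.values, 0.5))
        qw = quantize(const, n_samples=100, n_levels=4096)
        assert len(set(qw.codes.tolist())) == 1

    def test_sine_peak_at_quarter_period_address(self):
        qw = quantize(WaveformSpec("F"), n_samples=100, n_levels=4096)
        assert qw.n_samples == 100
        assert qw.codes[25] == qw.codes.max() == 4095

    @pytest.mark.parametrize("kind", "ACDEF")
    @pytest.mark.parametrize("n_levels", [16, 4096])
    def test_round_trip_error_bound(self, kind, n_levels):
        spec = WaveformSpec(kind)
        qw = quantize(spec, n_samples=100, n_levels=n_levels)
        t = np.linspace(0.0, 1.0, 100, endpoint=False)
        truth = eval_waveform(spec, np.where(t == 0, 1e-15, t))
        err = np.abs(dequantize(qw) - truth)
        assert err.max() <= 0.5 / (n_levels - 1) + 1e-12

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            quantize(WaveformSpec("F"), n_samples=1)
        with pytest.raises(ValueError):
            quantize(WaveformSpec("F"), n_levels=1)

    def test_ram_table_layout(self, tmp_path):
        qw = quantize(WaveformSpec("F"), n_samples=100, n_levels=256)
        path = tmp_path / "ram.txt"
        qw.to_ram_table(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 100
        assert lines[0].split() == ["0", str(int(qw.codes[0]))]
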