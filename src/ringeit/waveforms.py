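"""Excitation waveform library.

Six normalized periodic excitation waveforms (named A-F, ordered by
increasing energy) plus a symmetric exponential pulse, as used by a
waveform-reconfigurable electrical tomography emitter.  All waveforms take
values in [0, 1] over one period 1/f and are scaled by an amplitude A > 0
when driving a load:

====  =======================================================  ==========
kind  u_k(t) on one period (x = f t)                           E_k(1)
====  =======================================================  ==========
A     (e^{10x}-1)/(e^5-1) on (0,1/2], mirrored on (1/2,1]      9.8689e-2
B     (u_F + u_A - a)/b, scaled back to [0,1]                  2.8252e-1
C     2x^2 + 1/2 on (0,1/2]; -2x^2 + 4x - 3/2 on (1/2,1]       3.0000e-1
D     x (rising ramp)                                          3.3333e-1
E     1 - x (falling ramp)                                     3.3333e-1
F     1/2 + 1/2 sin(2 pi x) (offset sine)                      3.7500e-1
====  =======================================================  ==========

The signal energy is E = integral of |u(t)|^2 over one period, so for an
amplitude-scaled wave A*u_k the energy is A^2*E_k(f), and every closed form
carries a 1/f factor: E_k(f) = E_k(1)/f.

The exponential pulse is u_exp(t) = A*exp(-B*|2 f t - 1|): a symmetric
spike of height A at mid-period whose tails decay with rate B.  Its Fourier
cosine series (the pulse is even about t = 1/(2f)) is

    u_exp(t) ~ (A/B)(1 - e^-B)
               + 2AB sum_n ((-1)^n - e^-B) / (B^2 + (pi n)^2) cos(2 pi f n t)

which this module both evaluates analytically and cross-checks by
quadrature.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "WaveformSpec",
    "SampledWaveform",
    "QuantizedWaveform",
    "FourierApprox",
    "eval_waveform",
    "compose_waveform_B",
    "waveform_energy",
    "closed_form_energy",
    "energy_composite_identity",
    "fourier_approx_exp",
    "quantize",
    "dequantize",
    "sample_waveform",
    "KINDS",
    "SCALING_GRID_POINTS",
    "QUAD_ABS_TOL",
]

KINDS = ("A", "B", "C", "D", "E", "F", "EXP")

#: grid resolution used to locate the min/max of u_F + u_A when scaling
#: the composite waveform B back to [0, 1]; the sum is smooth so this is
#: far more resolution than the 5-digit energy target needs.
SCALING_GRID_POINTS = 100_000

#: absolute tolerance for adaptive quadrature of waveform energies.
QUAD_ABS_TOL = 1e-10

_E5 = math.exp(5.0)


@dataclass(frozen=True)
class WaveformSpec:
    """Analytic excitation waveform: identity, amplitude, frequency.

    Parameters
    ----------
    kind:
        One of ``A``-``F`` (normalized table waveforms) or ``EXP``
        (symmetric exponential pulse).
    amplitude:
        Voltage scale A > 0 multiplying the normalized shape.
    frequency:
        Fundamental frequency f in Hz (> 0); the period is exactly 1/f.
    exp_factor:
        Decay rate B > 0 of the exponential pulse; ignored for kinds A-F.
    """

    kind: str
    amplitude: float = 1.0
    frequency: float = 1.0
    exp_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown waveform kind {self.kind!r}; expected one of {KINDS}")
        if not (self.amplitude > 0):
            raise ValueError("amplitude must be > 0")
        if not (self.frequency > 0):
            raise ValueError("frequency must be > 0")
        if self.kind == "EXP" and not (self.exp_factor > 0):
            raise ValueError("exp_factor must be > 0")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def breakpoints(self) -> np.ndarray:
        """Interior points of one period where the waveform is only
        piecewise smooth (branch joints / discontinuities)."""
        if self.kind in ("A", "C", "EXP"):
            return np.array([0.5 * self.period])
        return np.array([])

    def __call__(self, t):
        return eval_waveform(self, t)


@dataclass(frozen=True)
class SampledWaveform:
    """One period of a waveform on a strictly increasing sample grid."""

    sample_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.sample_times, dtype=float)
        vv = np.asarray(self.values, dtype=float)
        if st.ndim != 1 or st.shape != vv.shape or st.size < 2:
            raise ValueError("sample_times and values must be 1-D, equal length >= 2")
        if not np.all(np.diff(st) > 0):
            raise ValueError("sample_times must be strictly increasing")
        object.__setattr__(self, "sample_times", st)
        object.__setattr__(self, "values", vv)

    @property
    def n_samples(self) -> int:
        return self.sample_times.size

    @property
    def period(self) -> float:
        return float(self.sample_times[-1] - self.sample_times[0])

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.sample_times, self.values])
        np.savetxt(path, arr, delimiter=",", header="t,value", comments="")


@dataclass(frozen=True)
class QuantizedWaveform:
    """Integer-coded waveform as loaded into the emitter's waveform RAM.

    The hardware maps one period onto 100 RAM addresses by default, so
    ``n_samples`` defaults to 100; ``n_levels`` is the DAC code range.
    """

    codes: np.ndarray
    n_levels: int
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if not np.issubdtype(codes.dtype, np.integer):
            raise ValueError("codes must be integers")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if codes.min() < 0 or codes.max() > self.n_levels - 1:
            raise ValueError("codes out of range [0, n_levels-1]")
        object.__setattr__(self, "codes", codes)

    @property
    def n_samples(self) -> int:
        return self.codes.size

    def to_ram_table(self, path) -> None:
        """Write an ``address code`` text table mirroring the RAM layout."""
        with open(path, "w") as fh:
            for addr, code in enumerate(self.codes):
                fh.write(f"{addr} {int(code)}\n")


@dataclass(frozen=True)
class FourierApprox:
    """Truncated cosine series: mean term + ``n_terms`` harmonics."""

    mean: float
    cosine_coefficients: np.ndarray  # harmonics n = 1 .. n_terms
    frequency: float

    @property
    def n_terms(self) -> int:
        return self.cosine_coefficients.size

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.mean)
        for n, a_n in enumerate(self.cosine_coefficients, start=1):
            out = out + a_n * np.cos(2 * np.pi * self.frequency * n * t)
        return out


def _phase(t, f: float) -> np.ndarray:
    """Map times to normalized phase x = f*t in (0, 1], period-wrapped.

    x = 0 is identified with x = 1 so that every branch interval is
    half-open on the left, matching the (0, 1/(2f)], (1/(2f), 1/f]
    branch convention.
    """
    x = np.mod(np.asarray(t, dtype=float) * f, 1.0)
    return np.where(x == 0.0, 1.0, x)


@functools.lru_cache(maxsize=32)
def _composite_scaling(frequency: float) -> tuple[float, float]:
    """Scaling constants (a, b) of the composite waveform B at a given f:
    a = min(u_F + u_A), b = max(u_F + u_A) - a over one period."""
    f = frequency
    t = np.linspace(0.0, 1.0 / f, SCALING_GRID_POINTS, endpoint=False)
    s = _eval_kind("F", t, f) + _eval_kind("A", t, f)
    a = float(s.min())
    b = float(s.max()) - a
    if b <= 0:
        raise ValueError("degenerate composite waveform: max(u_F+u_A) <= min(u_F+u_A)")
    return a, b


def _eval_kind(kind: str, t, f: float, exp_factor: float = 5.0) -> np.ndarray:
    x = _phase(t, f)
    if kind == "A":
        return np.where(
            x <= 0.5,
            (np.exp(10.0 * x) - 1.0) / (_E5 - 1.0),
            (np.exp(10.0 - 10.0 * x) - 1.0) / (_E5 - 1.0),
        )
    if kind == "B":
        a, b = _composite_scaling(f)
        return (_eval_kind("F", t, f) + _eval_kind("A", t, f) - a) / b
    if kind == "C":
        return np.where(x <= 0.5, 2.0 * x**2 + 0.5, -2.0 * x**2 + 4.0 * x - 1.5)
    if kind == "D":
        return x
    if kind == "E":
        return 1.0 - x
    if kind == "F":
        return 0.5 + 0.5 * np.sin(2.0 * np.pi * x)
    if kind == "EXP":
        return np.exp(-exp_factor * np.abs(2.0 * x - 1.0))
    raise ValueError(f"unknown waveform kind {kind!r}")


def eval_waveform(spec: WaveformSpec, t):
    """Evaluate ``spec`` at time(s) ``t`` (seconds), period-wrapped.

    Kinds A-F return values in [0, amplitude]; branch boundaries belong to
    the first branch (half-open intervals (0, 1/(2f)] and (1/(2f), 1/f]).
    """
    scalar = np.isscalar(t)
    out = spec.amplitude * _eval_kind(spec.kind, t, spec.frequency, spec.exp_factor)
    return float(out) if scalar else out


def sample_waveform(
    spec: WaveformSpec, n_samples: int, *, include_breaks: bool = False
) -> SampledWaveform:
    """Sample one period of ``spec`` on an equispaced grid.

    With ``include_breaks`` an extra node is inserted a relative 1e-12
    after every jump location so that piecewise-linear interpolation of the
    samples represents the discontinuity sharply instead of smearing it
    over one sample interval (needed for high-accuracy convolution).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    T = spec.period
    t = np.linspace(0.0, T, n_samples)
    if include_breaks:
        eps = 1e-12 * T
        jumps = []
        # period wrap is a jump unless u(0+) == u(1/f)
        u0 = eval_waveform(spec, eps)
        uT = eval_waveform(spec, T)
        if abs(u0 - uT) > 1e-12 * spec.amplitude:
            jumps.append(0.0)
        interior = [
            b
            for b in spec.breakpoints()
            if abs(eval_waveform(spec, b) - eval_waveform(spec, b + eps)) > 1e-12 * spec.amplitude
        ]
        # each jump needs the node at the jump (left value, by the
        # half-open branch convention) and one just after (right value)
        extra = [j + eps for j in jumps if 0.0 <= j < T]
        extra += [x for j in interior for x in (j, j + eps)]
        if extra:
            t = np.unique(np.concatenate([t, extra]))
    # t = 0 wraps to the end-of-period value under the half-open branch
    # convention, making the sampled period seamless when tiled
    vals = eval_waveform(spec, t)
    return SampledWaveform(t, np.asarray(vals))


def compose_waveform_B(frequency: float, n_samples: int) -> SampledWaveform:
    """Build the composite waveform B = (u_F + u_A - a) / b on one period.

    The scaling constants map the raw sum back to [0, 1]: a is its minimum
    and b its range, located on a dense grid of ``SCALING_GRID_POINTS``.
    """
    if not (frequency > 0):
        raise ValueError("frequency must be > 0")
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    spec = WaveformSpec("B", frequency=frequency)
    return sample_waveform(spec, n_samples)


def closed_form_energy(kind: str, frequency: float = 1.0) -> float | None:
    """Closed-form one-period energy E_k(f) where one exists (else None)."""
    f = frequency
    if kind == "A":
        return (math.exp(10.0) - 4.0 * _E5 + 13.0) / (10.0 * f * (_E5 - 1.0) ** 2)
    if kind == "C":
        return 3.0 / (10.0 * f)
    if kind in ("D", "E"):
        return 1.0 / (3.0 * f)
    if kind == "F":
        return 3.0 / (8.0 * f)
    return None


def waveform_energy(wave, frequency: float | None = None) -> float:
    """Energy of one period, E = integral |u(t)|^2 dt over [0, 1/f].

    ``wave`` is a :class:`WaveformSpec` (adaptive quadrature, split at
    branch boundaries) or a :class:`SampledWaveform` (trapezoid rule on the
    sample grid).  Quadrature is accurate to well beyond 5 significant
    digits (absolute tolerance ``QUAD_ABS_TOL``).
    """
    if isinstance(wave, SampledWaveform):
        return float(np.trapezoid(wave.values**2, wave.sample_times))
    spec = wave
    if frequency is not None and frequency != spec.frequency:
        spec = WaveformSpec(spec.kind, spec.amplitude, frequency, spec.exp_factor)
    if not (spec.frequency > 0):
        raise ValueError("frequency must be > 0")
    T = spec.period
    edges = np.concatenate([[0.0], spec.breakpoints(), [T]])
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        # Gauss-Kronrod nodes are interior, so the period-wrap convention
        # at t = 0 is never sampled
        val, _ = quad(
            lambda t: eval_waveform(spec, t) ** 2,
            lo,
            hi,
            epsabs=QUAD_ABS_TOL,
            epsrel=1e-12,
            limit=200,
        )
        total += val
    return total


def energy_composite_identity(frequency: float = 1.0) -> float:
    """Energy of waveform B from the expansion of the scaled sum,

        E_B = (1/b^2) [ E_F + E_A + a^2/f
                        + 2 * integral (u_F u_A - a u_F - a u_A) dt ],

    used as an independent cross-check of direct quadrature."""
    f = frequency
    a, b = _composite_scaling(f)
    uf = WaveformSpec("F", frequency=f)
    ua = WaveformSpec("A", frequency=f)
    cross, _ = quad(
        lambda t: (
            eval_waveform(uf, t) * eval_waveform(ua, t)
            - a * eval_waveform(uf, t)
            - a * eval_waveform(ua, t)
        ),
        0.0,
        0.5 / f,
        epsabs=QUAD_ABS_TOL,
        limit=200,
    )
    cross2, _ = quad(
        lambda t: (
            eval_waveform(uf, t) * eval_waveform(ua, t)
            - a * eval_waveform(uf, t)
            - a * eval_waveform(ua, t)
        ),
        0.5 / f,
        1.0 / f,
        epsabs=QUAD_ABS_TOL,
        limit=200,
    )
    E_F = closed_form_energy("F", f)
    E_A = closed_form_energy("A", f)
    return (E_F + E_A + a**2 / f + 2.0 * (cross + cross2)) / b**2


def fourier_approx_exp(
    amplitude: float, exp_factor: float, frequency: float, n_terms: int
) -> FourierApprox:
    """Truncated Fourier cosine series of the exponential pulse.

    The pulse A*exp(-B|2ft-1|) is even about mid-period, so its Fourier
    series is cosine-only with mean (A/B)(1-e^-B) and harmonic amplitudes
    2AB((-1)^n - e^-B)/(B^2 + (pi n)^2); these are exact (they agree with
    numerical quadrature of the Fourier integrals to roundoff).
    """
    A, B, f = amplitude, exp_factor, frequency
    if not (A > 0 and B > 0 and f > 0):
        raise ValueError("amplitude, exp_factor and frequency must all be > 0")
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    n = np.arange(1, n_terms + 1)
    coeffs = 2.0 * A * B * ((-1.0) ** n - math.exp(-B)) / (B**2 + (np.pi * n) ** 2)
    mean = A / B * (1.0 - math.exp(-B))
    return FourierApprox(mean=mean, cosine_coefficients=coeffs, frequency=f)


def quantize(
    wave: SampledWaveform | WaveformSpec,
    n_samples: int = 100,
    n_levels: int = 4096,
) -> QuantizedWaveform:
    """Resample one period to ``n_samples`` equispaced points and round to
    the nearest of ``n_levels`` uniform levels spanning [0, amplitude].

    100 samples mirrors the emitter RAM layout (one period in addresses
    0-99); 4096 levels is the package's default 12-bit code depth.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if isinstance(wave, WaveformSpec):
        amplitude = wave.amplitude
        t = np.linspace(0.0, wave.period, n_samples, endpoint=False)
        vals = eval_waveform(wave, np.where(t == 0.0, 1e-15 * wave.period, t))
    else:
        amplitude = float(np.max(np.abs(wave.values)))
        if amplitude == 0.0:
            amplitude = 1.0
        T = wave.period
        t = wave.sample_times[0] + np.linspace(0.0, T, n_samples, endpoint=False)
        vals = np.interp(t, wave.sample_times, wave.values)
    codes = np.rint(np.clip(vals / amplitude, 0.0, 1.0) * (n_levels - 1)).astype(np.int64)
    return QuantizedWaveform(codes=codes, n_levels=n_levels, amplitude=amplitude)


def dequantize(qw: QuantizedWaveform) -> np.ndarray:
    """Map integer codes back to waveform values in [0, amplitude]."""
    return qw.codes.astype(float) / (qw.n_levels - 1) * qw.amplitude


def waveform_metadata(spec: WaveformSpec) -> dict:
    """JSON-ready metadata for a waveform (kind, scale, frequency, energy)."""
    return {
        "kind": spec.kind,
        "amplitude": spec.amplitude,
        "frequency": spec.frequency,
        "energy": spec.amplitude**2 * waveform_energy(spec),
    }


def export_waveform(spec: WaveformSpec, csv_path, json_path=None, n_samples: int = 1000) -> None:
    """Write a (t, value) CSV table and optional JSON metadata."""
    sample_waveform(spec, n_samples).to_csv(csv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(waveform_metadata(spec), fh, indent=2)
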