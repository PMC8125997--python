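"""SISO RC impedance response simulation.

The single-input single-output test load is a series (R, C) divider whose
output is the capacitor voltage.  Its transfer function is
H(s) = 1/(RCs + 1): one real pole at -1/(RC), unit DC gain, impulse
response h(t) = (1/RC) e^{-t/RC}.  In the time domain,

    dy/dt = (1/RC) (u(t) - y(t)),

and the series current is i = (u - y)/R.  Two independent solution paths
are provided: stiff ODE integration (Radau, restarted at waveform branch
points) and the exact exponential-integrator evaluation of the
variation-of-constants solution

    y(t) = y(0) e^{-t/RC} + (1/RC) * integral_0^t u(s) e^{-(t-s)/RC} ds

with the input taken piecewise-linear between samples and each linear
segment integrated analytically.  Post-processing offers a zero-phase
Butterworth low-pass filter and Welch power spectral density estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.integrate import solve_ivp

from .waveforms import SampledWaveform, WaveformSpec, eval_waveform

__all__ = [
    "RCSeriesModel",
    "TransferFunction",
    "SimResult",
    "transfer_function",
    "simulate_response",
    "convolution_solution",
    "tile_periods",
    "phase_portrait",
    "postprocess_signal",
]


@dataclass(frozen=True)
class RCSeriesModel:
    """Series resistor-capacitor load: Z1 = R (ohm), Z2 = C (farad)."""

    resistance: float
    capacitance: float

    def __post_init__(self) -> None:
        if not (self.resistance > 0):
            raise ValueError("resistance must be > 0")
        if not (self.capacitance > 0):
            raise ValueError("capacitance must be > 0")

    @property
    def tau(self) -> float:
        """Time constant RC in seconds."""
        return self.resistance * self.capacitance


@dataclass(frozen=True)
class TransferFunction:
    """H(s) as polynomial coefficients plus derived pole/gain data."""

    numerator: np.ndarray
    denominator: np.ndarray
    poles: np.ndarray
    dc_gain: float
    tau: float

    def impulse_response(self, t):
        """h(t) = (1/RC) e^{-t/RC} for t >= 0, zero for t < 0."""
        t = np.asarray(t, dtype=float)
        return np.where(t >= 0, np.exp(-np.clip(t, 0, None) / self.tau) / self.tau, 0.0)

    def frequency_response(self, omega):
        """H(j*omega)."""
        s = 1j * np.asarray(omega, dtype=float)
        return np.polyval(self.numerator, s) / np.polyval(self.denominator, s)


@dataclass
class SimResult:
    """Aligned time series of excitation u, response y and current i."""

    times: np.ndarray
    u: np.ndarray
    y: np.ndarray
    i: np.ndarray
    model: RCSeriesModel
    method: str = "radau"
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.u) == len(self.y) == len(self.i) == n):
            raise ValueError("times, u, y, i must have equal length")

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.u, self.y, self.i])
        np.savetxt(path, arr, delimiter=",", header="t,u,y,i", comments="")


def transfer_function(model: RCSeriesModel) -> TransferFunction:
    """Transfer function of the series RC divider, H(s) = 1/(RCs + 1)."""
    tau = model.tau
    return TransferFunction(
        numerator=np.array([1.0]),
        denominator=np.array([tau, 1.0]),
        poles=np.array([-1.0 / tau]),
        dc_gain=1.0,
        tau=tau,
    )


def _input_callable(wave, n_periods: int):
    """Return (u(t) callable, period, interior restart points per period)."""
    if isinstance(wave, WaveformSpec):
        T = wave.period
        breaks = wave.breakpoints()
        return (lambda t: eval_waveform(wave, t)), T, breaks
    if isinstance(wave, SampledWaveform):
        T = wave.period
        t0 = wave.sample_times[0]

        def u(t):
            tp = np.mod(np.asarray(t, dtype=float) - t0, T) + t0
            return np.interp(tp, wave.sample_times, wave.values)

        return u, T, np.array([])
    raise TypeError("wave must be a WaveformSpec or SampledWaveform")


def simulate_response(
    model: RCSeriesModel,
    wave,
    n_periods: int = 3,
    points_per_period: int = 512,
    y0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimResult:
    """Integrate dy/dt = (u - y)/RC with the implicit Radau method.

    The exponential-pulse and table waveforms make the system stiff, so an
    implicit stiff solver is used; integration restarts at every waveform
    branch point (and period wrap) so discontinuities never sit inside a
    solver step.  Output is resampled on a uniform grid via dense output.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if points_per_period < 32:
        raise ValueError("points_per_period must be >= 32")
    u, T, breaks = _input_callable(wave, n_periods)
    tau = model.tau

    edges = np.concatenate([[0.0], np.sort(breaks), [T]])
    segs = []
    for p in range(n_periods):
        for lo, hi in zip(edges[:-1], edges[1:]):
            segs.append((p * T + lo, p * T + hi))

    t_out = np.linspace(0.0, n_periods * T, n_periods * points_per_period + 1)
    y_out = np.empty_like(t_out)
    y_out[0] = y0
    y_cur = y0
    for lo, hi in segs:
        # evaluate u strictly inside the segment so the half-open branch
        # convention at the edges cannot leak the neighbouring branch value
        pad = 1e-13 * T

        def rhs(t, y, lo=lo, hi=hi):
            tc = min(max(t, lo + pad), hi - pad)
            return np.atleast_1d((u(tc) - y[0]) / tau)

        sol = solve_ivp(
            rhs,
            (lo, hi),
            [y_cur],
            method="Radau",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"Radau failed on [{lo}, {hi}]: {sol.message}")
        mask = (t_out > lo) & (t_out <= hi)
        if mask.any():
            y_out[mask] = sol.sol(t_out[mask])[0]
        y_cur = float(sol.y[0, -1])

    u_out = np.asarray(u(np.where(t_out == 0.0, 1e-13 * T, t_out)), dtype=float)
    i_out = (u_out - y_out) / model.resistance
    return SimResult(t_out, u_out, y_out, i_out, model, "radau", rtol, atol)


def tile_periods(sw: SampledWaveform, n_periods: int) -> tuple[np.ndarray, np.ndarray]:
    """Tile a one-period sample set into an ``n_periods``-long series."""
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    T = sw.period
    t0 = sw.sample_times[0]
    # drop the duplicate period endpoint when tiling
    tt = sw.sample_times[:-1] - t0
    vv = sw.values[:-1]
    times = np.concatenate([tt + p * T for p in range(n_periods)] + [[n_periods * T]])
    values = np.concatenate([vv] * n_periods + [[sw.values[-1]]])
    return times, values


def convolution_solution(model: RCSeriesModel, u_samples, y0: float = 0.0) -> np.ndarray:
    """Exact exponential-integrator solution for piecewise-linear input.

    ``u_samples`` is a :class:`SampledWaveform` or a ``(times, values)``
    pair.  Between consecutive samples the input is linear, for which the
    variation-of-constants integral has the closed form

        y_{k+1} = a y_k + u_k (1-a) + du_k (1 - RC(1-a)/h_k),   a = e^{-h_k/RC},

    so the only approximation is the piecewise-linear model of u itself.
    Returns y on the input sample grid.
    """
    if isinstance(u_samples, SampledWaveform):
        t, u = u_samples.sample_times, u_samples.values
    else:
        t, u = (np.asarray(a, dtype=float) for a in u_samples)
    if t.size == 0:
        raise ValueError("empty input")
    if t.size == 1:
        return np.array([y0], dtype=float)
    tau = model.tau
    h = np.diff(t)
    if np.any(h <= 0):
        raise ValueError("sample times must be strictly increasing")
    x = h / tau
    em = -np.expm1(-x)  # 1 - e^{-x} without cancellation
    a = 1.0 - em
    # 1 - (1 - e^{-x})/x, series branch for small steps where the direct
    # expression loses all significant digits
    ramp = np.where(x < 1e-4, x / 2.0 - x**2 / 6.0 + x**3 / 24.0, 1.0 - em / np.where(x == 0, 1, x))
    du = np.diff(u)
    b = u[:-1] * em + du * ramp
    y = np.empty_like(t)
    y[0] = y0
    if np.allclose(h, h[0], rtol=1e-9, atol=0.0):
        # uniform grid: the recurrence is a first-order IIR filter
        zi = np.array([a[0] * y0])
        y[1:], _ = signal.lfilter([1.0], [1.0, -a[0]], b, zi=zi)
    else:
        acc = y0
        for k in range(h.size):
            acc = a[k] * acc + b[k]
            y[k + 1] = acc
    return y


def phase_portrait(
    sim: SimResult, scaled: bool = False, period: float | None = None
) -> dict[str, np.ndarray]:
    """Planar trajectories (u,y), (u,i), (i,y) after transient discard.

    The discarded transient is the longer of 5 RC times and 2 input
    periods (when ``period`` is given), capped so at least the final tenth
    of the simulation is kept.  With ``scaled`` each variable is affinely
    mapped to [0, 1]; a constant variable makes that map degenerate and
    raises an error naming the variable.
    """
    t = sim.times
    span = t[-1] - t[0]
    discard = 5.0 * sim.model.tau
    if period is not None:
        discard = max(discard, 2.0 * period)
    keep = t >= t[0] + min(discard, 0.9 * span)
    data = {"u": sim.u[keep], "y": sim.y[keep], "i": sim.i[keep]}
    if scaled:
        for name, arr in data.items():
            lo, hi = float(arr.min()), float(arr.max())
            if hi - lo <= 1e-300 or (hi - lo) < 1e-12 * max(abs(hi), abs(lo)):
                raise ValueError(f"variable {name!r} is constant; cannot scale to [0, 1]")
            data[name] = (arr - lo) / (hi - lo)
    return {
        "uy": np.column_stack([data["u"], data["y"]]),
        "ui": np.column_stack([data["u"], data["i"]]),
        "iy": np.column_stack([data["i"], data["y"]]),
    }


def postprocess_signal(
    series: np.ndarray,
    fs: float,
    cutoff: float = 1e5,
    psd: bool = False,
    order: int = 4,
    nperseg: int | None = None,
):
    """Zero-phase low-pass filtering and optional Welch PSD.

    A 4th-order Butterworth filter applied forward-backward (zero phase)
    with default 100 kHz cutoff; the PSD uses a Hann window with 50%
    overlap.  Returns ``filtered`` or ``(filtered, (freqs, density))``.
    """
    x = np.asarray(series, dtype=float)
    if not (fs > 2.0 * cutoff):
        raise ValueError("sampling rate must exceed twice the cutoff (Nyquist)")
    sos = signal.butter(order, cutoff, fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    if not psd:
        return filtered
    if nperseg is None:
        nperseg = min(x.size, max(256, x.size // 4))
    freqs, dens = signal.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    return filtered, (freqs, dens)
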