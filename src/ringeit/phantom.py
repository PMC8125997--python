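"""Synthetic electrolyte-tank phantoms and measurement generation.

Emulates the tank experiments used to validate the tomograph: a circular
electrolyte tank with 16 equidistant ring electrodes, measured over the
256 dedicated-electrode quadruples with waveform-modulated excitation.
Phantoms are a homogeneous ("empty") tank, a cylinder in the center, and
insulating rocks placed in front of named electrodes (the tank contents
the device was tested with).

The forward model is quasi-static, so the time structure of a measurement
row enters as a multiplicative waveform modulation of the DC solution:

    Y[r, w] = v_r * u(t_w) / u_max + noise,

where v_r is the forward solution for quadruple r, u the selected
excitation waveform sampled over one period at W points, and the noise is
zero-mean white Gaussian sized to a requested SNR (in dB, on RMS signal
power; the device specification is 90 dB).  Optionally each row can be
passed through the first-order RC response to mimic the low-pass lag of
the acquisition chain (off by default).

Default conductivities are 1.0 S/m background and 0.01 S/m inclusions
(insulating rock in saline); only the location of the contrast matters
for the localization checks, and both values are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import RCSeriesModel, convolution_solution
from .configs import ConfigSet, ElectrodeRing
from .fem import DEFAULT_CURRENT, ConductivityField, ForwardSolver, TriMesh
from .profiles import MeasurementSet
from .waveforms import WaveformSpec, eval_waveform

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "simulate_measurement_set",
    "DEFAULT_BACKGROUND_SIGMA",
    "DEFAULT_INCLUSION_SIGMA",
    "DEFAULT_SNR_DB",
]

DEFAULT_BACKGROUND_SIGMA = 1.0
DEFAULT_INCLUSION_SIGMA = 0.01
DEFAULT_SNR_DB = 90.0
#: rocks sit at 0.8 of the tank radius in front of their electrode,
#: with radius 0.1 of the tank radius
ROCK_RADIAL_FRACTION = 0.8
ROCK_RADIUS_FRACTION = 0.1
CYLINDER_RADIUS_FRACTION = 0.2


@dataclass(frozen=True)
class PhantomSpec:
    """Conductivity phantom: background plus circular inclusions.

    ``inclusions`` lists (center angle [rad], radial position as a
    fraction of the tank radius, inclusion radius as a fraction of the
    tank radius).
    """

    kind: str
    background_sigma: float = DEFAULT_BACKGROUND_SIGMA
    inclusion_sigma: float = DEFAULT_INCLUSION_SIGMA
    inclusions: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("empty", "center_cylinder", "rocks"):
            raise ValueError("kind must be 'empty', 'center_cylinder' or 'rocks'")
        if not (self.background_sigma > 0 and self.inclusion_sigma > 0):
            raise ValueError("conductivities must be > 0")
        for ang, rfrac, rad in self.inclusions:
            if not (rad > 0):
                raise ValueError("inclusion radius must be > 0")
            if rfrac + rad > 1.0 + 1e-12:
                raise ValueError(
                    f"inclusion at angle {ang:.3f} (r={rfrac}, radius={rad}) "
                    "extends outside the tank"
                )

    @classmethod
    def empty(cls, **kw) -> "PhantomSpec":
        return cls(kind="empty", **kw)

    @classmethod
    def center_cylinder(
        cls, radius_fraction: float = CYLINDER_RADIUS_FRACTION, **kw
    ) -> "PhantomSpec":
        return cls(kind="center_cylinder", inclusions=((0.0, 0.0, radius_fraction),), **kw)

    @classmethod
    def rocks_near(
        cls,
        electrodes: tuple[int, ...],
        ring: ElectrodeRing,
        radial_fraction: float = ROCK_RADIAL_FRACTION,
        radius_fraction: float = ROCK_RADIUS_FRACTION,
        **kw,
    ) -> "PhantomSpec":
        """Rocks placed in front of the named (1-based) electrodes."""
        incl = tuple(
            (ring.angle_of(e), radial_fraction, radius_fraction) for e in electrodes
        )
        return cls(kind="rocks", inclusions=incl, **kw)


def make_phantom(spec: PhantomSpec, mesh: TriMesh) -> ConductivityField:
    """Rasterize a phantom onto the mesh: an element takes the inclusion
    conductivity when its centroid falls inside any inclusion disk."""
    sigma = np.full(mesh.n_elements, spec.background_sigma)
    cent = mesh.centroids()
    R = mesh.radius
    for ang, rfrac, rad in spec.inclusions:
        center = R * rfrac * np.array([np.cos(ang), np.sin(ang)])
        inside = np.linalg.norm(cent - center, axis=1) < R * rad
        sigma[inside] = spec.inclusion_sigma
    return ConductivityField(sigma)


def simulate_measurement_set(
    mesh: TriMesh,
    phantom: ConductivityField,
    cfg: ConfigSet,
    waveform: WaveformSpec,
    W: int = 100,
    snr_db: float = DEFAULT_SNR_DB,
    seed: int = 0,
    current: float = DEFAULT_CURRENT,
    rc_filter: RCSeriesModel | None = None,
) -> MeasurementSet:
    """Waveform-modulated measurement matrix Y (N x W) over ``cfg``.

    Each quadruple's quasi-static response v_r is modulated by one period
    of the excitation waveform sampled at W points (normalized to its
    peak), optionally low-pass filtered through a first-order RC response,
    then corrupted by white Gaussian noise at ``snr_db`` decibels relative
    to the RMS of the noiseless matrix.  ``snr_db=inf`` (or None) disables
    noise.  Fully reproducible for a fixed seed.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    v = ForwardSolver(mesh, phantom).measure(cfg, current)
    t_w = np.arange(W) / (W * waveform.frequency)
    u = np.asarray(eval_waveform(waveform, np.where(t_w == 0.0, 1e-13 / waveform.frequency, t_w)))
    u = u / waveform.amplitude  # normalized modulation in [0, 1]
    if rc_filter is not None:
        u = convolution_solution(rc_filter, (t_w, u), y0=u[0])
    Y = np.outer(v, u)
    if snr_db is not None and np.isfinite(snr_db):
        if not (snr_db > 0):
            raise ValueError("snr_db must be positive (or None/inf for noiseless)")
        rms = float(np.sqrt(np.mean(Y**2)))
        noise_sd = rms * 10.0 ** (-snr_db / 20.0)
        rng = np.random.default_rng(seed)
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    return MeasurementSet(
        Y=Y,
        configs=cfg,
        sample_times=t_w,
        waveform={
            "kind": waveform.kind,
            "amplitude": waveform.amplitude,
            "frequency": waveform.frequency,
            "snr_db": snr_db,
            "seed": seed,
            "current": current,
        },
    )
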