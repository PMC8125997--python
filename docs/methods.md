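# Methods

This note records the models implemented in `ringeit`, their assumptions,
the defaults and why, the numerical choices, and what the synthetic tank
does and does not emulate.

## Excitation waveforms

Six periodic waveforms, normalized to [0,1] over one period 1/f and
indexed A–F by increasing one-period energy E_k(f) = ∫₀^{1/f}|u_k|²dt:

| k | u_k(t), x = ft | E_k(f) |
|---|----------------|--------|
| A | (e^{10x}−1)/(e⁵−1) on (0,½], (e^{10−10x}−1)/(e⁵−1) on (½,1] | (e^{10}−4e⁵+13)/(10f(e⁵−1)²) |
| B | (u_F+u_A−a)/b with a = min(u_F+u_A), b = range | quadrature |
| C | 2x²+½ on (0,½], −2x²+4x−3/2 on (½,1] | 3/(10f) |
| D | x | 1/(3f) |
| E | 1−x | 1/(3f) |
| F | ½+½sin(2πx) | 3/(8f) |

Branch intervals are half-open on the left; the branch point belongs to
the *first* branch, so waveform C is genuinely discontinuous at
mid-period (value 1 → 0) and is not "repaired". Times wrap with the same
convention: t = 0 is identified with t = 1/f.

Energy quadrature is adaptive Gauss–Kronrod split at branch points
(absolute tolerance 1e-10), comfortably beyond the 5-significant-digit
targets; closed forms are cross-checked against quadrature in the tests.
For composite B the scaling constants (a, b) are located on a fixed
100,000-point grid per period — u_F + u_A is piecewise smooth with one
kink, so the grid error is far below the 5-digit energy target. The
energy of B is additionally verified through the expanded identity
E_B = b⁻²[E_F + E_A + a²/f + 2∫(u_F u_A − a u_F − a u_A)dt].

**Exponential pulse.** The stiff test input is read as the symmetric
pulse u_exp(t) = A·e^{−B|2ft−1|}. This reading is forced by its Fourier
series: the pulse is even about mid-period, and its exact cosine
coefficients are

  a₀ = (A/B)(1−e^{−B}),  aₙ = 2AB·((−1)ⁿ−e^{−B})/(B²+(πn)²),

which the implementation computes analytically and the tests verify
against numerical Fourier integrals to 1e-8 relative. The package default
B = 5 gives a sharp spike (edge value e⁻⁵ ≈ 0.007 of the peak) that makes
the RC response convincingly stiff.

**Quantization.** One period is resampled to 100 points (mirroring a
100-address waveform RAM) and rounded to 2^bits uniform levels; the
default depth is 12 bits (4096 levels), a package choice — the DAC
register width is a free parameter, and the round-trip error bound
½/(n_levels−1) of full scale holds for any depth.

## RC response simulation

The SISO load is a series (R, C) divider, H(s) = 1/(RCs+1):
ẏ = (u−y)/RC, i = (u−y)/R. Two solution paths are deliberately
independent so each validates the other:

- **Stiff ODE**: Radau IIA (rtol 1e-8, atol 1e-10), restarted at every
  waveform branch point and period wrap so discontinuities never sit
  inside a solver step; dense output resamples onto a uniform grid.
- **Exponential integrator**: exact variation-of-constants stepping for
  piecewise-linear input. The step update uses expm1 and a series branch
  for 1−(1−e^{−x})/x below x = 1e-4; without these the tiny steps used to
  represent jumps lose ~4 significant digits to cancellation and cap the
  achievable agreement near 1e-5.

Jumps in sampled waveforms are represented by a node *at* the jump (left
value) plus a node a relative 1e-12 later (right value), so
piecewise-linear interpolation does not smear the discontinuity over a
sample interval. With 8192 samples per period the two paths agree to
≤ 1.3e-7 relative RMS for all waveforms at the bench configuration
(R = 218.6 Ω, C = 1 μF, f = 11.43 kHz).

Post-processing: 4th-order Butterworth applied forward–backward (zero
phase), default cutoff 100 kHz — the filter design is a package choice
pinned only by the observed spectral knee near 10⁵ Hz; Welch PSD with
Hann window and 50% overlap. Steady-state assertions discard the longer
of 5·RC and two periods.

## Configuration algebra

Electrode indexing is 1-based everywhere (e1…e16, e1 at angle 0,
counter-clockwise). The dedicated scheme requires L ≡ 0 (mod 4): the
repeating a,b,m,n role pattern must close around the ring. (The looser
stated condition L = 2M is necessary but not sufficient; divisibility by
4 is enforced.) Enumeration order is fixed — lexicographic for the full
set, row-major over role classes for the dedicated set — because
measurement vectors are indexed by configuration row and must be
reproducible. Adjacent/opposite schemes are represented only by their
counts L(L−3) and ratio (L²−3L+3)⁻¹, for comparison; they are not
simulated. Ratios use exact rational arithmetic.

## Forward model

Quasi-static, isotropic, real conductivity: ∇·(σ∇u) = 0 on the unit disk
(magnetic, capacitive and internal-source effects neglected). Choices
where the design was open:

- **Electrode model**: single-node point injection (gap model), not the
  complete electrode model. No contact-impedance data exists for the
  emulated system, and one-step *difference* imaging is insensitive to
  electrode-model bias common to v₀ and v₁. Contact impedance is out of
  scope.
- **Sensing**: differential, v = φ(m) − φ(n), since sensing is defined by
  an electrode pair.
- **Drive**: 100 μA default (the rated excitation current). The model is
  linear in the drive, so this is a pure scale factor.
- **Reference**: the pure-Neumann system is grounded at the center node
  for factorization and re-referenced to zero mean; any constant cancels
  in differential sensing.
- **Mesh**: structured concentric-ring triangulation — ring i of R at
  radius i/R carries L·i nodes, giving exactly L·R² elements of nearly
  identical area (CV ≈ 1–2%), a boundary node exactly at every electrode
  angle, and invariance under rotation by 2π/L. The construction is
  deterministic; target sizes 200/2000/3000/12000 map to 256/2304/3136/
  12544 elements. Homogeneous-disk boundary potentials converge to the
  analytic log-kernel closed form at O(h²): relative RMS 3.8e-2 / 1.7e-3 /
  5.5e-4 at 256 / 4096 / 12544 elements.
- **Jacobian**: adjoint method, J[r,e] = −∫_e ∇u_drive·∇u_sense dA with
  the sense field driven at unit current; one factorized solve per
  distinct drive or sense pair (32 for the dedicated set). Verified
  against central finite differences (δσ = 1e-6) to better than 1e-3
  relative on a 256-element mesh.

## Difference imaging

Δσ = −(JᵀJ + λ·diag(JᵀJ))⁻¹ Jᵀ (v₁ − v₀), solved by Cholesky
factorization of the regularized normal matrix (least-squares fallback
with a warning if not positive definite), never by explicit inversion.
Default λ = 0.01. The leading minus sign is implemented literally as
written above; combined with this package's drive/sense orientation it
renders insulating inclusions with positive Δσ. Since the acquisition
sign conventions of the emulated device are not fixed by any measurement
we can reproduce, all validation is *location-based* (extremum angle and
radius), never value- or sign-based.

Both renderings are always available: per-element values ("sharp") and
the vertex projection ("fuzzy"), where each vertex takes the unweighted
mean of incident elements — justified as a connectivity-only low-pass
filter because the mesh triangles are nearly equal in area.
Localization clusters the top decile of |Δσ| by edge connectivity and
reports magnitude-weighted centroids per cluster; the global centroid is
only meaningful for single structures.

## Potential profiles and the 64-response structure

Sorting responses ascending (stable, so ties keep acquisition order)
defines the profile; the permutation relative to a homogeneous reference
tracks inclusion effects (per-rank displacement, displaced-rank count,
Kendall-tau distance; reversal attains the maximum N(N−1)/2).

On the ideal homogeneous disk the axial symmetry argument runs: rotation
by 4 electrode positions (90°) maps the dedicated set onto itself, so the
16 excitation pairs produce only 4 distinct 16-response profiles — one
per excitation ring distance d ∈ {1,3,5,7} — i.e. 64 informative
responses among 256. `profile_structure` counts exactly this:
(distinct profile vectors, grouped at relative tolerance 1e-6) ×
(responses per profile).

A subtlety worth recording: the *raw scalar* count of numerically
distinct response values on the ideal disk is smaller than 64 (22
analytically), because two further exact symmetries create value
coincidences the profile argument does not count — the reflection
antisymmetry of the disk about each excitation pair's bisector pairs up
values *within* a profile, and reciprocity composed with a 2-electrode
rotation maps the dedicated set to itself *across* profiles. These
coincidences survive in any faithful symmetric simulation (FEM
reciprocity is exact to solver roundoff), which is why "unique responses"
is defined at the profile level; the raw scalar count is exposed
separately as `n_unique_values` and asserted in the tests.

## Synthetic tank generator

The generator emulates the electrolyte-tank measurement process: a unit
disk with 16 equidistant electrodes, the 256 dedicated quadruples, and
phantoms matching the physical setups — homogeneous ("empty"), a cylinder
at the center (radius 0.2·R), and insulating rocks in front of named
electrodes (center at 0.8·R along the electrode angle, radius 0.1·R; the
rock geometry is a package choice, as the physical rocks are shown but
not dimensioned). Conductivities default to 1.0 S/m background and
0.01 S/m inclusions — insulating rock in saline; the contrast sign is a
parameter since only contrast location is validated.

Time structure is multiplicative: Y[r,w] = v_r·u(t_w)/u_max + noise, one
waveform period sampled at W points. This is the quasi-static
approximation — the FEM is a DC solver and the waveform rides on top of
it; an optional first-order RC filter on the modulation mimics
acquisition lag (off by default). Noise is additive white Gaussian sized
on RMS signal power to a requested SNR (default 90 dB, the device
specification), seeded and reproducible; the empirical SNR of generated
sets is verified within ±1 dB over ≥ 10⁴ samples.

What the generator does *not* emulate: electrode–electrolyte
electrochemistry and drift, contact impedance, frequency-dependent
(complex) conductivity, 2D-vs-3D current spreading, and geometric
imperfections of a physical tank. Passing tests therefore demonstrate
correctness of the computational chain under its stated model, not
robustness to these physical effects.

## Problem sizes and tolerances used in validation

Mesh sizes in the tests and acceptance script are 256 elements for
brute-force oracles (finite-difference Jacobian, reciprocity), 2304 for
profile structure and noise calibration, 3136 for reconstruction
localization, and 12544 for the forward-convergence check — the smallest
sizes at which each property is cleanly exhibited. Key tolerances:
energies to 5 significant digits; ODE-vs-convolution agreement 1e-6
relative RMS; reciprocity 1e-9; adjoint-vs-finite-difference 1e-3;
dense-oracle pseudo-inverse 1e-10; localization ±22.5° (half the
inter-electrode spacing) and 0.3·R for the central target.

## Known limitations

- Point electrodes: absolute boundary potentials near drive electrodes
  carry the log singularity; only measurements away from drive nodes are
  validated against the closed form.
- One-step (linearized) reconstruction only; no iterative Gauss–Newton,
  no learned reconstructions.
- 2D geometry; no 3D electrode arrays.
- The quasi-static modulation model does not produce waveform-dependent
  *spatial* information; waveform choice affects energy and time series,
  not the reconstructed image, by construction.
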