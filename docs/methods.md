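# Methods

This note documents the physical model, the numerical choices and the
design decisions behind `qpamark`, and what the simulation studies do and
do not demonstrate.

## Light transport model

Light propagation is modeled with the 2D diffusion approximation

    μₐ(r) φ(r) − ∇·(κ(r) ∇φ(r)) = q₀(r),    κ = 1 / (3 (μₐ + μₛ′)),

valid when reduced scattering dominates absorption (μₛ′ ≫ μₐ; the
`OpticalMap` constructor warns when a map violates this). The absorbed
energy density is H = μₐ·φ, and the photoacoustic measurement is taken to
be H itself: acoustic detection and reconstruction are assumed ideal and
the Grüneisen parameter is set to 1, so all energy quantities are in
arbitrary but mutually consistent units. Scattering is assumed known and
is not estimated.

### Discretization

* **Mesh.** One linear (P1) node per pixel center; each grid cell is split
  into two right triangles by its main diagonal. Both triangles of a cell
  take the optical properties of the cell's top-left pixel, so phantom maps
  transfer to the mesh without interpolation.
* **Lumping.** The absorption mass matrix and the Robin boundary matrix are
  lumped (diagonal). This keeps the assembled operator an M-matrix, so the
  computed fluence is nonnegative, and it makes the discrete energy balance
  exact: absorbed power + boundary outflow = injected power (verified to
  machine precision on homogeneous media; within 2% for heterogeneous maps
  where nodal and element absorption differ).
* **Boundary condition.** Exit-only Robin condition φ + 2Aκ ∂φ/∂n = 0 with
  the Groenhuis/Schweiger internal-reflection coefficient
  A = (2/(1−R₀) − 1 + |cos θc|³) / (1 − |cos θc|²), R₀ = ((n−1)/(n+1))²,
  θc = arcsin(1/n), n = n_in/n_out. A = 1 for a matched boundary;
  A ≈ 2.35 for tissue/air (1.33/1.0). Any standard A produces the same
  exit-only behavior; inversion round trips are insensitive to the exact
  choice because the same operator is used forward and inverse.
* **Sources.** Gaussian nodal loads of standard deviation h (one pixel),
  truncated at 3h and normalized to unit total power, placed on the
  rectangle one grid spacing inside the boundary, equally spaced by
  perimeter arc length with a half-spacing offset (so they avoid corners).
  Default: ten sources. Note that this protocol ties the source positions
  and widths to the pixel size; grid-convergence checks therefore hold the
  *physical* source configuration fixed while refining the mesh.
* **Solver.** Sparse LU factorization per distinct μₐ map, reused across
  right-hand sides (all sources are solved as one combined load by
  superposition; the adjoint solve reuses the same factorization since the
  operator is self-adjoint). Relative residuals are checked against 1e-10.

### Measurement noise

H_M = H + e with e ~ N(0, σ²), σ² = mean(H²)/10^(SNR/10) — i.e. the SNR is
measured against the mean signal power of the noise-free map, reproducing
the usual "measured" AWGN convention. Noise is reproducible per seed
(numpy `default_rng`); SNR = +inf disables it.

## Inversion schemes

All iterative schemes minimize (explicitly or implicitly) the
volume-weighted misfit

    ε(μₐ) = ½ Σᵢ wᵢ (H_M − H_C(μₐ))ᵢ²,

with wᵢ the lumped nodal areas, starting from a uniform μₐ = 1e-10 mm⁻¹
(any value ≤ 1e-5 gives equivalent results) and clamping negative updates
to zero (noise can make H_M locally negative).

* **SIM** (simple iterative method): μₐ ← H_M / (φ(μₐ) + σ) elementwise.
  σ (default 0.002, fluence units) stabilizes low-fluence regions; it also
  sets the attainable misfit floor, ‖ΔH‖/‖H_M‖ ≈ σ/φ, so noise-free
  identifiability checks run with a near-zero σ. Stops at max_iter, an
  error threshold, or trace stagnation.
* **GBM** (gradient-based method): limited-memory quasi-Newton (L-BFGS,
  memory 10) with Armijo backtracking. The gradient is the *exact discrete*
  adjoint gradient: for pixel p,

      ∂ε/∂μₐ(p) = −w_p (H_M − H_C)_p φ_p + φ*ᵀ (∂A/∂μₐ(p)) φ,

  where A is the assembled system, ∂A/∂μₐ(p) contains the lumped-mass
  derivative and the κ-derivative of the stiffness (∂κ/∂μₐ = −3κ²), and φ*
  solves A φ* = w·μₐ·(H_M − H_C). This is the discrete counterpart of the
  continuum expression −φ(H_M−H_C) + φφ*; implementing it exactly is what
  lets finite differences of ε serve as a machine-precision oracle
  (relative agreement ≤ 1e-7 in practice, tested against ≤ 1e-4).
  The optimizer is written in-package because the marker reset and clamping
  must run *between* optimizer iterations, which black-box minimize APIs do
  not allow; it is validated against scipy's L-BFGS-B on a smooth test
  problem.
* **Marker handling.** With the marker engaged, GBM resets the marker
  pixels to the known μₐ^marker after every accepted iteration and
  re-evaluates there — the recorded error trace can therefore rise
  transiently (the characteristic early oscillation) while trending down.
  The constrained variant removes the marker pixels from the optimization
  space entirely (mathematically the equality constraint Aeq·x = beq on the
  marker set), so no reset is needed and marker pixels are bit-exact in the
  output.
* **Beer–Lambert route.** For the homogeneous two-layer geometry the
  relation μₐ·exp(μₐ·r) = (H_u/H_m)·μₐ^marker is solved in log form
  (ln x + x·r = ln c) by Newton from 1e-5 mm⁻¹ with a bracketing fallback —
  monotone, unique positive root, and immune to overflow at large μₐ·r.
  At r = 0 it reduces exactly to the equal-fluence estimate
  μₐ = (H_u/H_m)·μₐ^marker.

An "iteration" of GBM is one accepted quasi-Newton step (one gradient
evaluation plus line search); SIM iterations are single fixed-point
updates. Error traces store log‖H_M − H_C‖² (natural log of the weighted
squared misfit), one entry per iteration.

## Phantoms

The generators are deterministic (bit-identical regeneration) and scale
their geometry with the grid extent; marker-error options perturb only the
*prior* handed to the inversion, never the ground-truth map.

* **Nine-region phantom** (20×20 mm, 0.2 mm pixels default): background
  0.001 mm⁻¹, central marker disc (radius 2 mm) at 0.2 mm⁻¹, and nine
  absorption levels spanning [0.001, 0.2] mm⁻¹ with μₛ′ = 2 mm⁻¹ uniform.
  The exact inclusion layout is a documented package choice: scored regions
  1–3 (0.020, 0.075, 0.150 mm⁻¹; discs of radius 1.5 mm) sit 5 mm from the
  nearest boundary at distinct bearings; region 4 (0.075) is centred 13.5 mm
  below the top surface, laterally offset from the marker shadow; region 5
  is a background-level patch directly beneath the marker, inside its
  shadow; four unscored discs complete the nine levels.
* **Spectral phantom** (20 mm, five wavelengths): spectrally flat marker
  disc (0.2 mm⁻¹) inside an unknown-chromophore annulus with a unimodal
  synthetic spectrum (0.030, 0.055, 0.080, 0.060, 0.035 mm⁻¹, peak at the
  middle wavelength) in a background whose absorption rises monotonically
  (0.005 → 0.034 mm⁻¹) — enough wavelength-dependent attenuation to color
  the annulus's apparent spectrum appreciably. Three scored sub-regions sit
  beside, above and below the marker.
* **Carotid phantom** (24×24 mm, 0.15 mm pixels default): literature-style
  absorption values at 930 nm — blood 0.650 (the marker), lipid 0.013,
  muscle 0.050, superficial tissue 0.040, background tissue 0.040,
  background 0.008 mm⁻¹ — arranged as superficial-tissue and muscle layers
  at the top, the lumen-plus-lipid-ring at mid-depth, and a deep
  background-tissue disc near 15 mm.
* **Two-layer fixture**: closed-form scalar H pair for Beer–Lambert tests.

### What the synthetic studies do not show

The phantoms are 2D, piecewise-constant, and use the same diffusion model
for data generation and inversion — an "inverse crime" that is deliberate
here, because the studies probe the *inversion machinery* (marker handling,
convergence, depth dependence), not model adequacy. Real data add acoustic
reconstruction artifacts, 3D light transport, scattering heterogeneity and
model mismatch, none of which are represented. With ten sources around the
full perimeter the domain is well lit, so depth-dependent degradation is
milder than with one-sided illumination; the marker's benefit concentrates
in its own shadow and near low-fluence regions.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| μₛ′ | 2 mm⁻¹ | uniform reduced scattering of all phantoms |
| n_in / n_out | 1.33 / 1.0 | tissue / air refractive indices |
| sources | 10, unit power | Gaussian width = pixel size |
| SNR | 30 dB (nine-region), 40 dB (carotid) | measured-signal-power convention |
| max_iter | 700 | matches the full-scale comparison protocol |
| σ (SIM) | 0.002 | fluence regularizer |
| init μₐ | 1e-10 mm⁻¹ | uniform initial guess |
| tol_optimality | 1e-12 | projected-gradient infinity norm |

## Scoring

PSNR = 10·log₁₀(peak²/MSE) with the marker region excluded and peak
defined as the dynamic range (max − min) of the ground truth over the
included pixels — a deterministic, phantom-intrinsic choice that also makes
the score invariant to a common offset; absolute dB values are therefore
comparable only within this package, while method *orderings* are
meaningful. Region scores are arithmetic means over the labeled pixels with
percent error 100·|mean − truth|/truth. The equal-fluence baseline in
spectral studies applies μₐ = (H̄_region/H̄_marker)·μₐ^marker to region-mean
measured energies; spectral error statistics are mean ± SD of the absolute
μₐ error across wavelengths.

## Study problem sizes

The package's standard protocols are chosen to run on a single CPU in
minutes: the nine-region table uses the full 100×100 grid with 700
iterations over three noise realizations; the carotid study runs at half
resolution (80×80, 0.3 mm) with 450 iterations; the qualitative
method-ordering study uses a 50×50 grid with 150 iterations over five
seeds. Scaling down resolution and iterations this way leaves region means
within a few percent of the full-scale values because the scored regions
span many pixels and the inversions converge well before the caps.

## Known limitations

* 2D only; no radiative-transfer or Monte-Carlo reference transport.
* Scattering is never estimated; each wavelength is inverted independently.
* SIM's σ floor biases recovery where fluence is comparable to σ.
* The constrained GBM trusts the marker absolutely: a wrong marker value
  propagates into adjacent structures (quantified by the ±10% sensitivity
  study) rather than being averaged out.
* Absolute PSNR values depend on the peak convention and are not portable
  across implementations.
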