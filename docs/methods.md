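# Methods

## Physical model

A fiber with its symmetry axis along the Voigt "3" direction is modeled as a
transversely isotropic (hexagonal) elastic solid: five independent stiffness
constants C11, C33, C44, C13, C66, with the identity C12 = C11 − 2·C66.
Brillouin light scattering probes plane acoustic waves of wave vector q; the
Christoffel eigenproblem Γ·u = ρc²·u with Γ_ik = C_ijkl n_j n_l gives three
phase velocities per propagation direction n. For n at angle α to the axis
the spectrum factorizes into a pure transverse (PT) branch polarized normal
to the (q, axis) plane and a coupled quasi-longitudinal / quasi-transverse
(QL/QT) pair:

    ρ c_PT²      = C66 sin²α + C44 cos²α
    ρ c²_{QL,QT} = ½ [ C11 sin²α + C33 cos²α + C44
                   ± √( (C11 sin²α − C33 cos²α + C44 cos 2α)²
                        + 4 (C13 + C44)² sin²α cos²α ) ]

QL takes the + root. At α = 0° and 90° these reduce to the pure-mode limits
√(C33/ρ), √(C11/ρ), √(C44/ρ), √(C66/ρ), which anchor the inversion. The
closed forms are validated at every release against an independent route:
building the full 6×6 Voigt matrix, contracting to the 3×3 acoustic tensor
and diagonalizing (agreement < 10⁻⁹ relative over 200 random
positive-definite tensors × 181 angles).

### Scattering geometry

The probed wave vector depends on the geometry: q∥ = (4π/λ)sin(θ/2) in
transmission (index independent, in-plane), q⊥ = (4π/λ)√(n² − cos²(θ/2)) in
reflection (surface normal), and q_bs = 4πn/λ in backscattering, which also
describes the spurious "leakage" path that puts a strong quasi-longitudinal
peak into transmission spectra of fibers. The oblique angle of that leakage
phonon depends on how the fiber axis sits relative to the scattering plane;
published conventions are inconsistent, so the package exposes the
refraction-style helper α = arcsin(sinθ/n) but treats the leakage α as
user-supplied and never asserts a particular convention.

Velocities are c = 2πf/q with f the fitted peak center. By default the
anti-Stokes center is used (instrument displays customarily show that side);
when both sides of the doublet are fitted the mean absolute center can be
formed by the caller — the fit itself is sign-agnostic.

## Peak extraction

Spectra are modeled as a first-order polynomial baseline plus one plain
Lorentzian per phonon (the line shape used in the source analysis; a Voigt
option with fixed Gaussian width is available for instrument-resolution
convolution but off by default). Channels are weighted by 1/√counts,
matching photon-counting statistics; center uncertainties come from the fit
covariance scaled by √(χ²/dof), so over- or under-dispersed noise widens or
narrows them. Initial guesses come from local maxima of a 5-channel
median-filtered signal unless supplied. Peaks closer than a quarter of their
summed FWHM are flagged as overlapping. A 50-replicate Poisson Monte Carlo
in the test suite verifies that the 2σ interval covers the true center at
the nominal rate and that the center bias stays below 5% of the linewidth at
SNR ≈ 100.

## Tensor inversion

Given data {(α_i, branch_i, c_i, σ_i)}, the fit minimizes
Σ[(c_i − c_model)/σ_i]² over four constants (C11, C33, C44, C13) under the
C66 = C44 constraint — appropriate when the PT branch is only measurable
on-axis — or five with C66 free when off-axis PT data exist. Numerical
choices:

- **Positive definiteness by construction**: C13 = t·√((C11 − C66)·C33) with
  t ∈ (−0.999, 0.999) guarantees (C11 + C12)·C33 > 2·C13² at every iterate;
  diagonal constants are bounded in (0, 200] GPa. Optimizer:
  scipy's bounded trust-region reflective least squares, Jacobian-scaled.
- **Initialization** from pure-mode limits: C33 ← ρc_QL(α≈0)²,
  C11 ← ρc_QL(α≈90)², C44 ← ρc_PT², C13 ← 0.9·√(C11·C33) − C44; ten
  perturbed restarts before declaring non-convergence.
- **Sign convention**: velocities depend on C13 only through (C13 + C44)²,
  so the sign of C13 + C44 is not identifiable from velocity data; the
  conventional positive branch is reported.
- **Identifiability guard**: the design must contain QL points near α = 0
  and α = 90 and at least two oblique (15–75°) QL/QT points, since C13 only
  enters through the sin²α·cos²α coupling; otherwise the fit refuses with an
  error naming C13 rather than returning an unconstrained value.
- **Weights**: per-datum σ_c; generators record σ_c on every datum, and a
  1%-of-c default is recommended when a real dataset carries none.
- **Uncertainties** two ways: (i) covariance from the numerical Jacobian at
  the solution, scaled by χ²/dof; (ii) residual-resampling bootstrap
  percentile intervals (standardized residuals resampled with replacement,
  rescaled by each σ_i). The test suite checks the two agree within a factor
  of 1.5 on calibrated synthetic data. The source study prints ± values
  without stating their estimator, so neither route claims to replicate
  those numbers exactly.
- Strain states are fitted independently; no parameters are shared across
  strain levels.

## Engineering moduli

From the compliance S = C⁻¹ (computed numerically; closed forms are kept in
docstrings and verified in tests): E∥ = 1/S33, E⊥ = 1/S11, ν31 = −S13/S33 =
C13/(C11 + C12), ν12 = −S12/S11, G13 = C44, G12 = C66, and the Reuss
(uniform-stress) bulk modulus K = 1/Σ_{i,j≤3} S_ij — the unique standard bulk
modulus that reproduces both published values (8.5 GPa silkworm, 10.8 GPa
spider). Uncertainties are first-order delta-method propagations with a
central-difference Jacobian over whichever constants the covariance covers;
the hexagonal identity is kept exact under perturbation. Full precision is
retained internally; rounding to printed precision happens only in reports.

For isotropic media, M = ρc_L² and G = ρc_T², with ν = (r² − 2)/(2(r² − 1)),
r = c_L/c_T, E = 2G(1 + ν) and K = M − 4G/3. The source text prints a
Poisson-ratio formula with x = (c_L/c_T)² that does not reproduce its own
printed ν = 0.34; the standard relation above does, and is what the package
implements (treated as a typographical error in the source, not silently —
this note is the flag).

ν31 = 0.51 for silkworm silk exceeds the isotropic bound of 0.5. That is
admissible for anisotropic media and is reported unclamped; it is sensitive
to the C66 = C44 assumption (a smaller C66 lowers it).

## Reference constants and known inconsistencies

The fixture tensors store the published stiffness constants at full printed
precision (silkworm: ρ = 1350 kg/m³; film: c_L = 3235, c_T = 1590 m/s,
ρ = 1170 kg/m³). Spider dragline density is not given in the source study;
the fixtures use the literature value 1200 kg/m³, which affects only
synthetic velocity generation — tensor-to-moduli conversion is density-free.

Two cells of the published moduli table cannot be reproduced from the
published stiffness constants to half a unit in the last printed digit, and
the corresponding checks in the test suite are deliberately left failing
rather than loosened:

- silkworm 0% anisotropy ratio: the constants give E∥/E⊥ = 2.244 (and the
  printed moduli themselves give 23.4/10.4 = 2.25), but 2.3 is printed;
- spider 10% ν12: the printed row is internally inconsistent
  (C11 − 2·C66 = 6.0 vs printed C12 = 5.9, a rounding artifact), and no
  consistent rounding yields the printed 0.36 (±0.16); the constants give
  0.354.

For the same reason the tensor validator accepts C12 within 0.15 GPa of
C11 − 2·C66 instead of demanding exact equality.

## Synthetic data

Spectra: Lorentzian doublets at ±cq/2π on a flat baseline (default 10
counts, amplitude 1000, FWHM 0.8 GHz — peak SNR ≈ 100, similar to good
polarized fiber spectra) with Poisson counting noise; Gaussian detector
noise and noiseless modes are available. Velocity datasets: c(α) from the
closed-form model on a 10°-spaced grid for QL/QT/PT with i.i.d. Gaussian
errors, default σ_c = 50 m/s (≈1% of the axial QL velocity, consistent with
error bars no larger than plot symbols). Every random component draws from
its own substream spawned from the master seed — Poisson counts are drawn
per component and summed, which is distributionally identical to noise on
the total — so adding a peak never perturbs existing draws and fixed seeds
reproduce output bitwise.

The generator emulates peak positions, linewidths and counting statistics
only. It does not model elasto-optic coupling strengths (relative branch
intensities are free parameters), the tandem Fabry–Pérot transmission
function or free-spectral-range aliasing, fiber birefringence, or the
intensity decay of the axial longitudinal mode at larger q∥ seen in real
fiber spectra. Passing recovery tests therefore demonstrates correctness of
the geometry→velocity→tensor→moduli chain under the assumed noise model, not
robustness to instrument artifacts.

## Problem sizes

Default study sizes were chosen to give stable Monte-Carlo statements at
desk scale: 50 replicates for peak-fit calibration, 100 seeds for the tensor
recovery study, 200 random tensors × 181 angles for the closed-form vs
eigensolver equivalence, and 100–200 bootstrap replicates. The full test
suite runs in well under a minute on one CPU.
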