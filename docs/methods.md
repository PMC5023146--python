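# Methods

## The 2G cycle scheme

Active contraction shortens the zero-stress sarcomere length, so a single
reference configuration cannot describe both cardiac phases. The toolkit
models the RV cycle with two zero-load geometries:

* **Filling (diastole) phase** — the diastolic zero-load chamber is loaded
  from the begin-filling pressure `Pmin` to the end-filling pressure `Pdia`.
* **Ejection (systole) phase** — the (smaller) systolic zero-load chamber is
  loaded from the begin-ejection pressure `Pmax` down to the end-ejection
  pressure `Psys`.

The two isovolumic phases are skipped: at end-filling the model switches
instantaneously to the systolic chamber at `Pmax`, and at end-ejection back to
the diastolic chamber at `Pmin`. Volume is continuous across the switches
(both chambers are calibrated to the same measured volume pair) while stress
and strain jump — the jump is the model's representation of active tension
onset/release. The solver is quasi-static (inertia neglected), so the
solution is periodic by construction. A 1G companion model is the degenerate
case: one chamber loaded continuously `Pmin → Pmax → Pmin`, sharing the same
code path.

Zero-load is not zero-stress: residual stresses are ignored, and the
zero-load configuration is the computable surrogate for the reference state.

## Constitutive laws

Isotropic modified Mooney–Rivlin (patch/scar tissue) and transversely
isotropic Mooney–Rivlin (myocardium):

    W_iso   = c1 (I1 − 3) + c2 (I2 − 3) + D1 [exp(D2 (I1 − 3)) − 1]
    W_aniso = W_iso + K1/(2 K2) [exp(K2 (I4 − 1)^2) − 1]

with `I1, I2` the invariants of `C = FᵀF` and `I4 = n_f·C n_f` the squared
fiber stretch. A Fung-type exponential law in local fiber coordinates is
provided as the fitting target format for biaxial data, and
`fit_aniso_to_fung` converts it to the Mooney–Rivlin form by bounded
multi-start least squares on stress–stretch curves.

Two numerical choices deserve note:

* **Exponent grouping.** Some printed forms of these laws place the `−1`
  inside the exponential (`exp(D2(I1−3) − 1)`), which yields nonzero energy
  and stress at the reference state and contradicts the zero-load premise.
  The package groups the exponential so `W = 0` and `σ = 0` at identity; the
  literal alternative is available behind `literal_grouping=True` for
  comparison.
* **Incompressibility** is enforced exactly via a Lagrange pressure fixed by
  a traction-free direction, rather than a nearly-incompressible penalty:
  simpler, testable against finite-difference energy gradients (the suite
  checks agreement to 1e-5 relative), and indistinguishable from a stiff
  penalty at the pressures involved. The `K2 → 0` limit of the fiber term is
  handled analytically.

Default parameter sets (`ventricle_diastole`, `ventricle_systole`, `patch`,
`scar`) are configuration values at plausible stiffness scales (kPa); all
patient-specific stiffness is set by volume calibration, never taken from the
defaults as-is.

## Geometry quantification

Ventricles are contour stacks: ordered short-axis slices, each with a closed
inner and outer contour (cm), resampled to a canonical 100 points at equal
arc length with a fixed start-point convention (the +x axis crossing,
counter-clockwise). On this substrate:

* **Volumes** use disk summation (slice area × slice spacing, shoelace
  areas) — the cardiology reading of "Simpson's method", not Newton–Cotes.
* **Wall thickness** is the distance from each inner point to the outer
  contour along the outward inner normal (nearest ray intersection, with a
  flagged nearest-point fallback).
* **Curvatures** are unsigned, from least-squares circle fits over sliding
  windows: 7 of 100 points in-slice (circumferential), 5 slices along
  index-aligned meridians projected into the (ρ, z) plane (longitudinal).
  The window sizes are configuration; estimator choice is validated against
  analytic ellipse/sphere curvature to 2 %.
* **Quarter partition** cuts each slice into 4 contiguous runs of equal inner
  arc length.
* **Fiber fields** use a two-layer helical architecture (defaults −60°
  epicardial / +80° endocardial to the circumferential direction, split at
  half wall depth). Under the spherically symmetric forward model the
  equibiaxial wall state makes fiber stretch independent of the in-plane
  angle, so the angles affect only fiber-frame strain reporting — a
  documented limitation of the equivalent-chamber reduction.

## Pre-shrink (zero-load recovery)

The imaged geometry is pressurized; the zero-load geometry is recovered by
shrinking each slice toward its inner-contour centroid and reducing the slice
spacing in proportion (`axial_rate = inner_rate` by default). The outer
contour shrinks by the factor that conserves the wall cross-sectional area of
the slice (closed form for an annulus: `Ro′ = sqrt(Ro² − Ri² + ((1−r)Ri)²)`);
a `conserve="volume"` mode additionally compensates the axial contraction.
The shrink rate is iterated — secant updates with a bisection fallback, which
converges because the pressurized volume is smooth and strictly decreasing in
the rate — until re-pressurization reproduces the measured volume to < 0.5 %.
Starting rates are 2 % (diastole) and 15 % (systole, consistent with 10–15 %
sarcomere shortening). The planted-rate round-trip (shrink by a known rate,
inflate, recover) reproduces the rate to 1e-3.

## Forward model: equivalent-chamber inflation

The 3-D finite-element solve is replaced by the inflation of an
incompressible thick-walled sphere whose inner/outer radii are set by volume
equivalence with the contour stack. This is the package's largest deliberate
reduction: it preserves exactly the quantities the downstream analysis
consumes — the pressure–volume relation, transmural mean stress and strain,
and the inter-phase discontinuities — while admitting closed-form kinematics
(`r³ = R³ + ri³ − Ri³`) and exact oracles (thin-wall Laplace limit,
quadrature refinement, boundary-condition residuals). It does not resolve
regional stress concentrations, patch/scar geometry or the septum.

The inner radius at pressure `p` solves

    p = ∫_{ri}^{ro} 2 (σ_hoop − σ_rr) / r dr,

with `σ_hoop − σ_rr = (λ/2) dW̃/dλ` from the equibiaxial energy path
(the fiber term enters as its in-plane mean). The pressure integral uses
48-point Gauss–Legendre quadrature in the reference radius (doubling the
nodes changes volumes by < 1e-6 relative); transmural profiles use a
101-point trapezoid grid, giving radial-stress boundary residuals below
1e-3·p. Reported `Stress-P1` / `Strain-P1` are the maximum principal Cauchy
stress (= hoop stress under inflation) and Green–Lagrange strain,
volume-weighted across the wall — the weighting is a choice; area weighting
differs by < 1 % for these wall thicknesses. Landmark states are mapped back
onto the contour stack by dilating the inner contours to the deformed cavity
volume under wall-volume conservation, so wall thickness thins and
circumferential curvature falls as the chamber dilates.

## Patient calibration

Each phase must satisfy two volume constraints (minimum volume at the phase's
low pressure, maximum at its high pressure). A single multiplicative factor
on the stress-like parameters cannot always do this: scaling all stress-like
parameters by `f` is equivalent to rescaling pressure by `1/f`, so the shape
of the pressure–volume curve is invariant. Calibration is therefore a bounded
least-squares over three quantities — shrink rate, log stiffness factor, and
a log exponent scale multiplying the dimensionless stiffening exponents
(`D2`, `K2`) — with a weak prior holding the exponent scale at 1 so the
prescribed curve shape is kept whenever it suffices. The scalar
`scale_stiffness_to_volume` (bracketed root-find on the log factor, bounds
[1e-3, 1e3]) is retained for single-target adjustments. Calibrated landmark
volume errors are typically below 0.1 % (tolerance 0.5 %).

## Cohort statistics

Standard machinery behind a thin surface: Pearson correlation with the
t-transform p-value; unpaired Student t-test (equal-variance by default, as
named; Welch behind a flag); paired t-test with exact-equality shortcuts for
degenerate differences; and a random-intercept-per-patient linear
mixed-effects model (REML, Wald p on the fixed condition effect) for paired
model comparisons with patient–slice clustering, falling back to ordinary
regression when the between-patient variance collapses. Normality checks
(Shapiro–Wilk) are logged, never gating. The LME's type-I error is verified
by simulation to lie in [0.03, 0.07] at α = 0.05.

## Outcome prediction

Eight candidate predictors per patient: wall thickness, circumferential and
longitudinal curvature, RV end-diastolic volume, begin-ejection stress, and
the three stress differences begin-ejection minus end-filling / end-ejection
/ begin-filling. Every non-empty subset (255) is scored by logistic
regression under 2-fold cross-validation repeated 20 times; the AUC average
and its 95 % percentile interval come from 100 rounds of the whole procedure,
each round seeded deterministically from the base seed.

Design choices where the protocol is underdetermined:

* **Stratified folds** (4+4 per group) prevent single-class folds at n = 16;
  a non-stratified mode with re-drawing is available.
* **Held-out scores are pooled per repeat** before computing the AUC and the
  Youden-optimal cutoff (ties broken toward higher specificity); per-fold
  averaging is available as an alternative estimator.
* **A small ridge penalty** (1e-3 on z-scored predictors, intercept
  unpenalized) keeps the likelihood bounded on the many subsets that
  perfectly separate 16 patients. The Newton/IRLS solver uses step-halving
  for near-separable folds and is written in-package for speed (the full
  ranking performs ~10⁶ fits; numba accelerates it when present); it is
  cross-checked against an independent maximum-likelihood implementation at
  zero ridge.

## Fixtures and synthetic data

The published 16-patient tables (demographics, per-patient 1G/2G phase
stresses and strains, wall-thickness/curvature aggregates, begin-ejection
cohort metrics with outcome groups) ship as checksummed CSVs; every printed
summary row is recomputed from the per-patient rows in the test suite, which
doubles as a transcription check. The demographics table's overall mean row
reproduces only the worse-outcome group's EF change; it is transcribed as
printed and flagged, not corrected.

The synthetic ventricle is a truncated two-wall ellipsoid (defaults: semi-axes
3.0 × 2.5 × 4.5 cm, 0.5 cm wall, 12 slices × 100 points — a dilated-RV scale)
with optional radial noise. The synthetic cohort plants a group effect on
begin-ejection stress (ratio ≈ 1.6, the published group contrast) and builds
the EF change as a linear function of stress with Gaussian noise sized to hit
a target correlation (default −0.609); phase stresses follow the cohort-mean
phase ratios with lognormal jitter. Both are seed-deterministic. The cohort
generator is a statistical test instrument: it reproduces the cohort's
moment structure, not ventricular physiology, so passing tests demonstrate
the pipeline's statistical behaviour, not clinical validity. Problem sizes
in the test suite (12-slice stacks, 100-round CV, 500-simulation
calibrations) are chosen to exercise every code path at full protocol
fidelity on a single CPU.

## Known limitations

* The equivalent-chamber reduction removes all regional information; slice- 
  level stress/strain heterogeneity and patch/scar inclusions are out of
  scope (a coarse area-weighted mixture stiffness hook exists but is off by
  default).
* Pressure schedules are patient-specific inputs; the shipped defaults are
  placeholders at physiological magnitudes, not measurements.
* Exact per-patient constitutive parameters of the original cohort are not
  published; mechanics-side comparisons are therefore property-based
  (orderings, discontinuity structure, volume closure) rather than value
  reproductions, while all table-derived statistics are reproduced
  numerically.
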