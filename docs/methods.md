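# Methods

## Constitutive model and assumptions

The tissue is modelled as an incompressible, isotropic, hyperelastic solid.
Deformation states are described entirely by principal stretches
(λ₁, λ₂, λ₃); the right Cauchy–Green invariants are I₁ = Σλᵢ²,
I₂ = Σᵢ<ⱼ λᵢ²λⱼ², I₃ = Πλᵢ², with I₃ = 1 enforced on every uniaxial state.
Full deformation-gradient tensors are never materialised: the package's scope
is uniaxial loading, where principal-stretch space is complete.

The principal Cauchy stresses are σᵢ = λᵢ ∂W/∂λᵢ − p.  For uniaxial loading
along direction 1 with free lateral faces, incompressibility gives
λ₂ = λ₃ = λ^(−1/2) and the condition σ₂ = σ₃ = 0 determines the hydrostatic
pressure p = λ₂ ∂W/∂λ₂.  Substituting back yields closed-form axial stresses
for each supported family:

| family | W | uniaxial Cauchy stress |
|---|---|---|
| neo-Hookean | C10(I₁−3) | 2(λ²−λ⁻¹)C10 |
| Mooney–Rivlin | C10(I₁−3)+C01(I₂−3) | 2(λ²−λ⁻¹)(C10 + C01/λ) |
| Yeoh | Σₖ Ck0(I₁−3)ᵏ, k≤3 | 2(λ²−λ⁻¹)·W′(I₁) |
| Ogden order-N | Σₚ (μₚ/αₚ)(Σλᵢ^αₚ − 3) | Σₚ μₚ(λ^αₚ − λ^(−αₚ/2)) |

Engineering stress is T = σ/λ with λ = 1 + ε.  The tangent modulus at ε = 0
is 6(C10 + C01) for the invariant families and (3/2)Σμₚαₚ for Ogden (the
incompressible identity E = 3μ₀).  Sign convention is tension-positive
throughout; compression rigs log magnitude-positive curves, and fitting
converts those via ε → −ε, σ → −σ so one closed form serves both modes.

Anisotropy, compressibility, damage/plasticity and rate dependence are out of
scope: gland parenchyma measured at quasi-static rates (0.005–0.05 s⁻¹) shows
no significant rate or orientation effect, which is what justifies the
isotropic incompressible treatment.

Correctness of the closed forms is enforced by dual-route tests: explicit
pressure elimination (evaluate λᵢ∂W/∂λᵢ, zero the lateral stress) and a
central-finite-difference route through W itself must agree with the closed
form to 1e−10 / 1e−6 relative, over random coefficient draws of all four
families.

## Data reduction

Units are fixed package-wide: force N, length mm, time s, hence stress MPa.
Reduction is σ = F/A, ε = ΔL ⁄ L₀ with A the initial cross-section (circular
or rectangular).  Replicate curves are averaged by linear interpolation onto
a common strain grid restricted to the intersection of the replicate ranges —
piecewise-linear interpolation is ample at 125 Hz sampling, where adjacent
strain samples differ by ~4×10⁻⁵.

## Three-phase segmentation

Quasi-static compression curves of gland tissue are concave-up with three
stages: a low-stiffness linear toe (OA, slope k1 = E1), a nonlinear
transition (AB), and a stiff, approximately linear compacted stage (BC,
slope k2 = E2).  The compacted stage may include internal damage, so E2 is
reported as a curve slope with a `may_include_damage` flag, not as a purely
elastic constant.

The boundaries are found by a growing-window rule: A is the largest strain
such that the OLS line on [0, A] still counts as linear; B is the smallest
strain such that the line on [B, ε_max] counts as linear.  Window linearity
uses a **noise-corrected R²**:

    R²* = 1 − max(SSE − 1.5·NoiseSSE, 0) / Syy ≥ r_lin,   r_lin = 0.9995

where NoiseSSE = Σd²/6 estimates the window's noise floor from second
differences d of the stress samples (for iid noise on a locally linear
signal, E[Σd²] = 6(m−2)σ²; the factor 1.5 guards the estimator's sampling
error).  The correction matters: a plain R² threshold cannot distinguish
measurement noise from systematic curvature, so it either rejects noisy but
genuinely linear toe windows or silently swallows part of the curved
transition and biases the slopes by several percent.  With the correction,
the same threshold handles noiseless curves (boundaries essentially exact)
and 2%-noise curves (median slope errors ~1% toe, ~4% compacted over 100
seeds).  The noise-floor estimate assumes an approximately uniform strain
grid, which constant-rate sampling provides.  On a curve that is linear
throughout, the two windows overlap and the result is flagged `degenerate`
with E1 = E2 = the global slope.

Replicate statistics (mean, variance) use the n−1 sample variance — verified
against the published six-specimen summaries, which they reproduce to
printed precision.

## Hyperelastic calibration

The objective is unweighted least squares on engineering stress over the
curve's own strain grid (optional 1/|σ| relative weighting is available),
with R² = 1 − SS_res/SS_tot about the data mean.  For the neo-Hookean,
Mooney–Rivlin and Yeoh families the engineering stress is linear in the
coefficients, so the fit is an exact linear solve: the global optimum,
bitwise deterministic, with no starting values at all.  No positivity
constraint is placed on C20 (soft tissue routinely calibrates negative); a
non-monotone fitted response on the data range is reported as a stability
warning, not an error.

The Ogden exponents enter nonlinearly.  The fit multistarts from every pair
of exponents in a fixed grid {±2, ±4, ±8, 12}, profiles the moduli out by
linear least squares at each start, explores on a ≤400-point subsample with
loose tolerances, and refines the three best candidates on the full data —
deterministic and start-independent in practice.  A fitted parameter set
with Σμₚαₚ ≤ 0 (non-positive ground-state shear modulus) is reported as a
failure rather than returned as a material.

`compare_models` ranks families by R², breaking ties (differences below
1e−6 by default) in favour of fewer parameters — the parsimony criterion
used to select the Yeoh form for this tissue.

A note on the source data: the Yeoh coefficients calibrated on the full
compression curve imply a small-strain modulus 6·C10 ≈ 1.14×10⁻² MPa,
roughly 500× the directly measured toe modulus E1 ≈ 2.2×10⁻⁵ MPa.  That is a
property of calibrating a three-parameter polynomial to a curve spanning
five decades of stiffness, not a defect of either number; the package keeps
both quantities and never asserts them against each other.

## Prony-series relaxation

Under held strain ε₀, the relaxation modulus is G(t) = Σᵢ Eᵢe^(−t/τᵢ) + E∞,
so G(0) = ΣEᵢ + E∞ and G(∞) = E∞ = σ∞/ε₀.  Fitting operates on
G(t) = σ(t)/ε₀ with t = 0 at the end of the loading ramp (the series assumes
step strain, so the flagged ramp segment is excluded).  The solver is
bounded trust-region least squares with an analytic Jacobian: Eᵢ, E∞ ≥ 0,
τᵢ ∈ [dt, 100·T]; τ initialisation is log-spaced over [T/200, 2T]; moduli
initialise at an equal split of G(0) − G(T).  Fitted terms are returned
sorted by τ.

**Identifiability.**  E∞ and a slow Prony term are separable only if the
hold is long relative to the slowest time constant.  For the reference
four-term parameter set (τ_max = 2.89×10³ s), the Cramér–Rao bound computed
from the exact Jacobian shows that a 1000 s hold leaves E∞ with >1000%
relative uncertainty at any realistic sampling rate — no estimator can
recover it — while a 10⁴ s hold (~3.5·τ_max at 1 Hz) bounds every parameter
below 4%.  The recovery studies in the tests and the acceptance script
therefore use a 10⁴ s hold at 1 Hz with 1% multiplicative noise and 50
seeds (observed medians: E∞ ≈ 0.1%, Eᵢ ≤ 1.5%, τᵢ ≤ 4%).  The generator's
*protocol default* remains the bench protocol's 1000 s hold; analyses of
1000 s records should treat the fitted equilibrium term as an extrapolation,
and prefer E∞ = σ∞/ε₀ from the residual stress when only the long-term level
is needed.

A further scale caveat in the source data: the published four-term modulus
set sums to G(0) = 3.49 MPa, two orders of magnitude above the moduli
implied by the published relaxation stresses at ε₀ = 0.25 (~0.1 MPa
instantaneous).  The package implements both as printed and never asserts
one against the other.

## Tensile error analysis

Absolute error Δ = A − L (signed, MPa) and relative error η = |Δ|/L·100 (%);
the sign of a discrepancy lives in Δ only, matching how such comparison
tables are conventionally printed.  η is undefined (flagged, not raised)
when L = 0 with A ≠ 0, and defined as 0 when A = L = 0.  The table's mean
relative error averages over all rows including a zero-strain row.  The
closed-form uniaxial prediction deliberately ignores clamped-boundary
stress concentrations, so grip-mounted strip tests will systematically
exceed it at large strain; externally computed predictions (e.g. from a
finite-element solve) can be supplied as ordinary reduced records.

## Synthetic data generator

The generators emulate the bench protocol: cylindrical ⌀10 mm × 6 mm
specimens, 125 Hz logging, compression to 45% strain at 0.005 s⁻¹ (rate
affects only the time axis, mirroring the observed absence of rate effects),
relaxation ramp at 200 mm/min to ε₀ = 0.25 with a 1000 s hold, and
80 × 15 × 5 mm tensile strips at 2 mm/s.  Defaults: 6 replicates
(matching the published replicate count), 2% multiplicative Gaussian stress
noise, zero additive force-sensor noise (the reference rig uses a
high-precision transducer; the dominant scatter in soft-tissue testing is
signal-proportional), and 10% log-normal inter-specimen variability on
material coefficients (log-normal keeps coefficient signs stable; 10% is at
the conservative end of the ~16% CV seen across the published six
specimens).  All generators are pure functions of (config, seed).

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: preconditioning cycles and their transient
softening, dehydration drift over a test session, force-sensor drift,
clamped-boundary effects in tension, damage in the compacted phase, and any
genuine strain-rate dependence.

## Problem sizes and numerical choices

- Compression recovery study: 50 seeded curves, 10,001 samples each
  (ε ∈ [0, 0.4] sampled at 125 Hz), 2% noise; Yeoh fit is a linear solve,
  so the whole study runs in well under a second.
- Prony recovery study: 50 seeded records, 10⁴ samples each (1 Hz, 10⁴ s),
  1% noise; ~10 s total with the analytic Jacobian.
- Phase study: 100 seeded 600-point curves; milliseconds each.
- Optimizer tolerances: 1e−12 (xtol/ftol/gtol) for refinement stages, 1e−8
  for Ogden exploration; linear solves use `numpy.linalg.lstsq` with machine
  rcond.
- Degenerate inputs are first-class: zero-force records reduce to zero
  stress; constant-stress relaxation records fit to Eᵢ ≈ 0 with
  E∞ = σ/ε₀; purely linear compression curves segment as a flagged
  single phase.

## Known limitations

- The hyperelastic and viscoelastic descriptions are separate; no
  quasi-linear viscoelastic (hereditary-integral) coupling is attempted.
- E2 conflates elastic stiffening with possible tissue damage.
- The Ogden fit explores a fixed exponent grid; exotic optima outside
  |α| ≤ 12 would need a user-supplied start.
- Segmentation assumes a near-uniform strain grid for its noise-floor
  estimate; strongly non-uniform grids should be resampled first.
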