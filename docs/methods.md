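# Methods

## Scope and model

`aortaflow` implements a lumped, per-pulse-averaged model of the aorta as
an energy store for blood flow. The wall is a pre-stretched thin-walled
elastic cylinder, linearly elastic in the circumferential direction over
the physiological pressure window, with axial deformation neglected (the
axial modulus is much larger and the vessel is tethered by surrounding
tissue). Flow is laminar (λ = 64/Re) and pulse-averaged; no waveform is
resolved. These are the model's assumptions, not approximations the code
can relax.

Two independent routes to the stored energy are implemented and tied to
each other by an exact algebraic identity:

1. **Stress/strain route** — Δu = (σ_s−σ_d)(ε_s−ε_d)/2 from measured or
   synthetic curves, with σ from the constrained Laplace relation and
   engineering strains against the unstressed diameter.
2. **Pressure route** — Δu = φ²(α_s p_s − α_d p_d)²/8E from clinical
   pressures alone.

Under equal wall ratios and linear elasticity, route 1 equals route 2
times ((α+2)/α)²; the test suite asserts this to 1e-12 relative. The
residual factor reflects the α vs α+2 mismatch between the two published
forms; the pressure form is treated as authoritative when energies are
computed from pressures.

The flow chain V → Q → Q̄ follows the calibrated reading documented in
`docs/CALIBRATION.md`. The λ–V circularity (λ needs Re, Re needs V) is
closed in three selectable ways: `fixed_beta` (β supplied, the default for
the published examples which print β), `fixed_Re` (λ from a supplied
Reynolds number, β from the wall thinning h_d−h_s), and `self_consistent`
(β(V) ∝ 1/V, giving the closed form V = c − b; a dissipation exceeding the
drive raises a model-regime error rather than returning a negative
velocity). The self-consistent closed form is cross-checked against a
fixed-point iteration oracle in the tests.

## Parameters

| parameter | meaning | default | rationale |
| --- | --- | --- | --- |
| E [Pa] | circumferential secant modulus | 3.5·10⁵ | published reference vessel |
| φ [-] | expansion constraint coefficient, (0,1] | 0.0439–0.0565 | maps to 3–4% lumen area strain on the reference vessel |
| D, h [mm] | reference outer diameter, wall thickness | 32.0, 1.46 | ascending aorta, D/h ≈ 22 (thin-wall valid; warning below D/h = 10) |
| ρ [kg/m³] | blood density | 1050 | standard |
| μ [Pa·s] | dynamic viscosity | 4·10⁻³ | typical whole blood |
| η, K [-] | kinetic-energy and dissipation coefficients | 2, 1 | laminar flow |
| n [min⁻¹] | pulse rate | 72 | unprinted in the anchor example; adopted, overridable |
| γ | per-unit-volume weight | kgf convention (≡ ρ) | selected by calibration; SI γ = ρg available |
| L_eff [m] | effective compliance length | 6.0 | attributes a whole-tree volumetric compliance (≈1.8 ml/mmHg) to the aortic cross-section; chosen so the healthy cohort operates at ≈4% area strain, the same operating point as the reference vessel |

## Diastolic-pressure inversion

`solve_diastolic_pressure` finds the subject DBP at which the subject's
mean flow equals a reference cohort's (`equal_mean_flow`; per-pulse and
per-compliance matching rules are reserved enum stubs). The reference
cohort's compliance C fixes its operating area strain
ε_A = C·p̄/(L_eff·A_f) and hence φ = ε_A·E·h/(p̄·D).

For the subject's φ two policies exist, and the choice is the single most
consequential design decision in the package:

- **`iso_strain` (default).** The subject operates at the same area strain
  as the reference; its φ adapts to its own mean pressure,
  φ(p_d) = ε_A·E·h/(p̄(p_d)·D). This is the constant-operating-strain
  relation under which φ is negatively correlated with mean pressure, and
  it reproduces the published cohort inversion (94.3 mmHg) to printed
  precision. Physically it encodes strain homeostasis: the tree remodels
  so the aorta works at a preferred strain, and the constraint coefficient
  absorbs the pressure difference.
- **`from_compliance`.** The subject's φ comes from its own measured
  compliance via φ = C·E·h/(L_eff·A_f·D) and is independent of the
  candidate DBP. Under this policy the same cohort inputs give
  ≈90.8 mmHg — the two policies bracket the published value and the gap
  quantifies how much the answer depends on the φ convention.

The root is found by plain bisection on (1 mmHg, p_s − 1 mmHg) to
1e-3 mmHg (≤200 iterations), with a diagnostic error listing the flows at
both bracket ends when no sign change exists; tests cross-check the
bisection against `scipy.optimize.brentq` and assert round-trip recovery
of a known DBP on 100 seeded draws.

## Curve processing

Inflation curves (pressure vs outer diameter at fixed axial stretch) are
interpolated monotone piecewise-linearly and never extrapolated.
Stress–strain curves are fitted with the origin-anchored two-parameter
exponential σ = a(e^{bε}−1) — the functional form chosen for the
"exponential function" the measurements support — with deterministic
initialisation (b₀ from the log-stress slope of the upper third, a₀ from
the last point). Strain-energy integrals use the composite trapezoid on
tabulated knots (plus interpolated endpoints, refined to ≥200 panels) and
the closed-form antiderivative a(e^{bε}−1)/b − aε for fitted curves; the
two agree within 0.1% at 200 panels and converge to 1e-6 relative by 10⁵
panels. The linear-vs-integral comparison uses the full chord trapezoid
(σ_lo+σ_hi)/2·Δε against ∫σ dε over the same window, so both areas
measure the same region; it is zero for linear curves and positive for
convex ones.

## Synthetic data

No raw inflation or biaxial measurements are published, so the generators
emulate their qualitative shapes; all are deterministic under a seed.

- **Pressure–diameter:** bounded monotone sigmoid
  D(p) = D_o + (D_max−D_o)/(1+e^{−(p−p_half)/slope}) with
  truncated-normal noise accepted only if the curve stays non-decreasing
  (whole-curve rejection, cap 100). The three named segment fixtures
  (ascending, proximal, distal descending; axial stretches 1.2/1.3/1.4)
  are illustrative, not measured.
- **Stress–strain:** σ = a(e^{bε}−1) on [0, 0.4] (wall strain stays below
  0.4 at physiological load) with per-point truncated-normal noise
  resampled until the running curve is non-decreasing. Whole-curve
  rejection is infeasible at the 1 kPa noise the tests use, because the
  noise exceeds the flat low-strain increments; the per-point scheme
  biases the fitted (a, b) by well under 1%, which the parameter-recovery
  test bounds at 5%.
- **Cohorts:** truncated-normal draws per parameter with p_s > p_d
  enforced by rejection; defaults are clinically plausible ranges around
  the reference vessel.

What passing tests on these stand-ins show: the processing chain
(interpolation, fitting, integration, inversion) is correct on data of the
right shape and noise scale. What they do not show: anything about
biological variability, anisotropy, viscoelastic creep, or measurement
artefacts of real inflation rigs — none of which the generators emulate.

## Reproducibility of the published examples

`run_worked_examples` recomputes six published quantities under the single
frozen calibration and prints computed value, published value and
deviation. Three are reproduced: the cohort DBP inversion (94.28 vs
94.3 mmHg), the severe-hypertension flow excess (a lower-bound check:
+78% ≥ +31%), and — as calibration anchors with documented residuals — the
rest/normal flows (∓9–10%). The two remaining percentage comparisons
(+23% and −18.2% for fixed-SBP diastolic changes) are **not** reproduced
(+30.1% and −37.2% computed): jointly they would require the mean flow to
scale as PP^0.11·p̄^−1.46, which no reading of the flow equation — nor the
model's own monotonicity in pulse pressure — can produce. They are
reported with their deviations rather than refit.

## Numerical choices and degenerate inputs

- Equal systolic/diastolic pressure is a valid degenerate state: V = 0,
  Q̄ = 0, Δu = 0 (the model is entirely pulse-driven).
- Re > 2100 logs a laminar-assumption warning (it can fire during bracket
  probing in the inversion, where extreme candidate DBPs are evaluated);
  h_d < h_s warns and returns a negative β rather than raising.
- Wall incompressibility h_i·D_i = h·D is enforced to 1e-12 relative when
  geometry is derived from an area strain.
- All comparisons of dimensionless outputs (β, strains, relative flow
  changes) are invariant to the γ convention, the calibration constant
  and joint unit rescalings to 1e-10; the suite asserts this.

## Known limitations

- Per-pulse averaged only; no waveform, no wave reflection, no Windkessel
  parameter fitting, no 3-D fluid–structure interaction.
- Linear-elastic circumferential behaviour; no hyperelastic
  (Fung/Gasser-Ogden-Holzapfel) constitutive fitting and no
  viscoelasticity.
- The stationarity of the coupled energy functional at the closed-form
  velocity does not hold under any single fraction reading of the source
  expressions; `chi_stationarity_diagnostic` reports the defect as an
  informational number and nothing asserts it.
- The two flow anchors are mutually inconsistent with the equation family
  (see `docs/CALIBRATION.md`); absolute flows carry the documented ±10%
  calibration residual, while ratios and inversions (which the constant κ
  cancels out of) do not.
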