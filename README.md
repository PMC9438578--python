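# aortaflow

Arterial strain-energy and blood-supply modelling for cardiovascular
biomechanics.

The classical Windkessel picture treats the heart as the only power source
of the circulation and the arterial tree as a passive elastic buffer.
`aortaflow` implements the alternative view in which the deformed elastic
aorta is itself a second pump: the strain energy stored in the wall between
diastole and systole is returned to the blood as mechanical work. The
package turns clinically measurable parameters — systolic/diastolic
pressure, aortic diameter and wall thickness, circumferential elastic
modulus, heart rate, blood viscosity — into stored strain energy, a
characteristic flow velocity, per-pulse and per-minute blood supply, and
inverse estimates of diastolic pressure. It is intended for researchers in
hemodynamic modelling and for reproducing and probing lumped
pulse-pressure-driven blood-supply calculations.

## Model

For a thin-walled elastic cylinder (outer diameter `D_i`, wall `h_i` in
state `i ∈ {d, s}`) constrained by surrounding soft tissue with expansion
constraint coefficient `φ`, the circumferential stress is the constrained
Laplace stress

    σ_i = φ p_i D_i / (2 h_i),          α_i = D_i/h_i − 2,

and the strain energy density increment (SEDI) stored over one pulse is

    Δu = (σ_s − σ_d)(ε_s − ε_d)/2  =  φ²(α_s p_s − α_d p_d)² / 8E,

with `E` the circumferential secant modulus and engineering strains
referenced to the unstressed diameter. Balancing the released strain energy
against the kinetic energy of the accelerated blood and the wall-shear
dissipation (laminar friction factor λ = 64/Re) gives the characteristic
velocity — the flow distance per pulse —

    V = κ φ h (α_s p_s − α_d p_d) / (D γ (1+β)),
    β = 4 E λ (h_d − h_s) / (D (p_s − p_d) φ),

and the mean blood supply through the lumen area `A_f`

    Q̄ = n (1 + φ D p̄ /(E h)) A_f V,     p̄ = (2 p_d + p_s)/3,

where `n` is the pulse rate, `β` the coupling energy dissipation
coefficient and `κ` a frozen dimensionless calibration constant (see
`docs/CALIBRATION.md`). The expansion constraint coefficient is related to
the lumen area strain by `ε_A = φ p D/(E h)` and hence to arterial
compliance, which is how cohort compliance measurements enter the model.

Beyond the core relations the package ships: processing of inflation
(pressure–outer-diameter) and biaxial stress–strain curves, exponential
`σ = a(e^{bε}−1)` and linear-window fits, strain-energy integrals and the
linear-vs-nonlinear energy comparison, seeded synthetic generators for all
of those inputs, SEDI surfaces over (SBP, DBP) grids, one-parameter flow
sensitivity sweeps, and a bisection inversion of Q̄ for diastolic pressure
under an equal-mean-flow matching rule.

## Worked example

Normal-state ascending aorta (120/80 mmHg, E = 3.5·10⁵ Pa, D = 32.0 mm,
h = 1.46 mm, φ = 0.0565, β = 0.290):

```bash
$ cat normal.json
{"p_s_mmHg": 120, "p_d_mmHg": 80, "D_mm": 32.0, "h_mm": 1.46,
 "E_Pa": 3.5e5, "phi": 0.0565, "beta": 0.290}
$ aortaflow flow -c normal.json
```

```json
{
  "Qbar_L_per_min": 8.763087731865587,
  "Re": 1614.0378920115063,
  "V_m_per_pulse": 0.1762011628579623,
  "alpha_d": 19.917808219178085,
  "alpha_s": 19.917808219178085,
  "beta": 0.29,
  "lambda": 0.03965210501981434
}
```

The blood advances 0.176 m through the aortic cross-section per pulse,
i.e. 8.76 L/min at 72 pulses/min — cardiac-output scale — and the
pulse-averaged Reynolds number of ~1600 is comfortably laminar. The same
library call drives the published-example report:

```bash
$ aortaflow examples
                             quantity   computed  published  deviation_pct
                      rest_flow_L_min   4.744732       5.23      -9.278553
                    normal_flow_L_min   8.763088       7.95      10.227519
                hypertensive_dbp_mmHg  94.280373      94.30      -0.020814
severe_hypertension_flow_increase_pct  77.885258      31.00     151.242767
    low_vs_high_dbp_flow_increase_pct  30.057405      23.00      30.684368
   isolated_diastolic_flow_change_pct -37.242388     -18.20    -104.628504
```

Deviations from the published values are computed and printed, never
absorbed by per-example refitting; `docs/methods.md` discusses which of
them are reproducible under a single consistent reading of the model and
which are not.

The inverse solver recovers the diastolic pressure of a hypertensive
cohort (SBP 156 mmHg, 69.1 bpm) whose mean flow matches a healthy cohort
(123/72 mmHg, 64.8 bpm, compliance 1.78 ml/mmHg):

```bash
$ aortaflow invert-dbp
{"dbp_mmHg": 94.28037345288262, "phi_policy": "iso_strain"}
```

Other subcommands: `sedi`, `fit-curves`, `sweep`, `synth` (seeded synthetic
curves and cohorts), all emitting machine-readable JSON/CSV.

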