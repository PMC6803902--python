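# Methods

## Physical model

The solvers treat the headspace vial as a closed system at equilibrium. Up
to four phases are present: the sample liquid (model wine: 12% v/v aqueous
ethanol, 5 g/L tartaric acid, pH 3.5), the headspace gas, the SPME fiber
coating, and optionally a second liquid phase — a glass ampoule holding the
internal-standard solution, whose glass wall volume is treated as zero. Each
compound distributes according to dimensionless partition constants,

- `K1 = C_s/C_h` (sample liquid/gas, a Henry-type constant),
- `K2 = C_h/C_f` (gas/fiber; small K2 means strong fiber enrichment),
- `K3 = C_h/C_i` (gas/ampoule liquid).

With these orientations the closed-form headspace concentration is
`C_h = C_0 V_s / (K1 V_s + V_h + V_f/K2 + V_i/K3)`. When the ampoule matrix
is the same model wine as the sample, the two liquids must carry equal
concentrations at equilibrium, which forces `K3 = 1/K1`; that is the
default, and it makes the `V_i/K3` term equal `K1 V_i`, consistent with
treating the ampoule as a second sample-like liquid. Note the orientation:
`K3` is defined gas-over-liquid while `K1` is liquid-over-gas, so "identical
matrices" means `K3 = 1/K1`, not `K3 = K1`.

Three solver modes reflect the experimental designs:

- **three_phase** — the ISTD is co-dissolved with the sample (conventional
  HS-SPME). The two liquids are merged into one phase; a dissolved
  cyclodextrin binds analytes and standards alike.
- **four_phase_equilibrium** — all four phases fully equilibrate, including
  liquid-to-liquid transfer through the gas phase. This is the long-time
  limit in which the ampoule no longer protects the standard.
- **four_phase_short_extraction** — the working assumption of the four-phase
  method: extraction is short enough that cross-liquid transfer is
  negligible (`C_i V_i = 0` for sample compounds and symmetrically
  `C_s V_s = 0` for ampoule compounds). Each liquid equilibrates only with
  headspace and fiber.

Endpoint equilibrium only: there is no kinetic or agitation model, and
temperature enters solely as a label on the constants (no van't Hoff
extrapolation). A property test checks that dividing `K1` by 100 — the
magnitude of the reported 35→80 °C change for guaiacol — strictly raises
`C_h`, which is the expected qualitative direction.

## Cyclodextrin binding

Complexation is 1:1 with a single binding site, confined to the sample
phase, and the complex is non-volatile — the standard treatment for CD
inclusion of small phenols. For a trial free-host concentration `h` each
guest's distribution is the linear closed form with an extra sample-phase
sink `K1 V_s K_b h`; the host balance `h + Σ K_b h C_s(h) = total host` is
strictly increasing in `h`, so the root is bracketed on `[0, total host]`
and found with Brent's method at machine-precision relative tolerance
(≤ 200 iterations; the closed-form quadratic for a single guest and a
brute-force grid over `h` serve as independent oracles in the tests).
Ethanol (12% v/v) is not modelled as a competing guest; if ethanol–CD
association is appreciable, every fitted `K_b` is an *apparent* constant
conditioned on the wine matrix.

## Parameters and defaults

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `V_total, V_s, V_i, V_f` | 20, 6, 0.5, 6.6e-4 | mL | the studied vial geometry; β_i = 27, β_s = 2.25 |
| `K1` | 2.2e4 | — | literature water/air value for guaiacol near ambient; applied uniformly since per-phenol constants for model wine are not tabulated. Retention percentages are insensitive to `K1` because `K1·V_s` dominates the denominator both with and without CD |
| `K2` | 1e-3 | — | fiber enriches 1000× over gas; keeps fiber depletion of the analyte below ~10⁻⁵ of the total, so sampling is non-perturbing |
| `K3` | `1/K1` | — | identical liquid matrices (see above); configurable for other ISTD matrices |
| `K_b` | derived | L/mol | inverted from the bundled benchmark's 25 g/L retention percentages through the four-phase model (13–151 L/mol for β-CD) |
| analyte / ISTD spikes | 1 / 10 | mg/L | the validated working concentrations |
| CD molar masses | from formula | g/mol | α/β/γ = C36H60O30 / C42H70O35 / C48H80O40 |

Isotopologues inherit their parent's `K1/K2/K3/K_b`: deuteration does not
measurably change partitioning or cavity affinity, which is precisely the
mechanism by which the co-dissolved standard nullifies the three-phase
assay. All internal computation is in mol/L and mL; mg/L and g/L are
converted at the boundary using molar masses computed from molecular
formulas (conventional atomic weights, D = 2.014 g/mol).

## Quantification choices

- Calibration lines are ordinary least squares on **per-level mean RPAs**
  (levels 0–2 mg/L, nine levels, triplicate). Averaging replicates per level
  before regression matches how replicated calibration series are
  conventionally summarized and reported; `fit_calibration` accepts raw
  replicate points too (`aggregate_replicates=False`). R² is the squared
  Pearson correlation of the fitted points.
- Retention uses means of replicate RPAs
  (`100·mean(RPA_treated)/mean(RPA_control)`), not per-replicate ratios, and
  a treatment's overall figure is the unweighted mean over compounds.
- Group comparison is classic one-way ANOVA with **unadjusted** pairwise
  two-sample t-tests at α = 0.05, as in the benchmark study's analysis; a
  Holm-adjusted option exists but is off by default. The compact letter
  display uses greedy insertion in descending-mean order.
- Negative quantified concentrations are reported as-is with a warning —
  they are diagnostic of blank-level signals.
- The bundled benchmark table is stored verbatim, including two cells whose
  printed percentages are internally inconsistent with their printed RPAs
  (the p-cresol column, off by a roughly constant factor, and the eugenol
  5 g/L α-CD cell, which duplicates the 25 g/L value). Retention
  computations use the RPA ratios; no code forces agreement for those cells.

## Synthetic data generator

The generator stands in for the GC-MS instrument. Expected fiber
concentrations come from the equilibrium solver and a peak area is
`response_factor · C_f · exp(ε)` with `ε ~ N(0, σ²)`,
`σ = √ln(1+CV²)` — the exact lognormal scale for a multiplicative factor
with coefficient of variation CV (at the CVs in scope, ≤ 10%, this is
numerically indistinguishable from σ ≈ CV). Noise is independent per peak;
analytes in the same vial share their standard's area, as on a real
chromatogram, but there is no additional shared-extraction covariance (a
known simplification — real isotope dilution cancels common-mode fiber
variability, so independent noise is conservative for RPA precision). The
response factor (10⁸ counts·L/mol) cancels from every RPA.

The generator does **not** emulate chromatographic reality: no peak shapes,
drift, carryover, fiber aging, matrix interferences, or inter-fiber response
differences. Passing tests therefore demonstrate the correctness of the
equilibrium/quantification logic under the stated statistical model, not
robustness to instrument pathology.

Design defaults mirror the study conditions: triplicates; calibration at
0–2 mg/L (nine levels) for the three compounds with their own labelled
isotopologues; dose experiments at 5 and 25 g/L for α/β/γ-CD with all eight
phenols at 1 mg/L and the standards isolated in the ampoule; the three-phase
scenario with the standards co-dissolved and inheriting their parents'
binding constants. Each run table is driven by a single seeded generator and
the seed is recorded in the output metadata.

## Binding-constant inference

At fixed dose the predicted percent-of-control is strictly decreasing in
`K_b`, so one observed percentage identifies one constant: the fit is
Brent's method on log10 K_b over [1e-6, 1e9] L/mol with the model residual
checked against 1e-8. Percentages ≥ 100 return `K_b = 0` (warning above
100). Host depletion is carried exactly rather than assumed negligible
(total host 2.2e-2 mol/L vs. ~8e-6 mol/L per guest at the default
conditions, so it is in fact small). Because the dose experiment co-spikes
all eight phenols, the recovery harness inverts each simulated experiment
with the **competitive** joint fit (nested refitting with the co-guests'
current estimates; it converges in a few sweeps given the tiny depletion);
at CV = 0 this recovers the generating constants to better than 1e-6
relative, which would not hold for one-at-a-time fits. Compounds with true
retention above 90% are flagged: `d(percent)/d(K_b)` is nearly flat there,
so their estimates are intrinsically unstable.

## Problem sizes

The test suite and the acceptance script use: 200 simulated calibration
series (27 areas each) for the linearity pass rate; 100 simulated dose
experiments (2% CV, n = 3) for binding recovery; a 10⁶-point (refined)
brute-force grid for the free-host oracle; exact rational arithmetic for all
triangle-test tails (n = 38). The full suite runs in well under a minute on
one core.

## Known limitations

- Uniform default `K1` across phenols; per-compound constants are
  configurable but not bundled.
- No 2:1 or higher-order complexes, no CD–ethanol competition, no CD
  solubility ceiling (relevant above ~18 g/L for β-CD in water; the model
  treats the stated dose as fully dissolved).
- The four-phase "short extraction" mode is an idealization — the full
  equilibrium mode shows what happens when its assumption fails, but the
  crossover time scale is outside the model.
- Benchmark-derived binding constants are apparent, dose-specific inversions
  through this model; they are not calorimetric constants.
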