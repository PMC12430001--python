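# Methods

## The model

The package treats a temperature–composition solubility grid as 21 (or
however many) independent van't Hoff problems plus one cosolvency model
across them.

**Per-composition regression.** At each mass fraction `w1` the mole-fraction
solubility x3 is assumed log-linear in reciprocal temperature over the
studied range — i.e. the apparent enthalpy of solution is treated as
temperature-independent (no ΔCp curvature term; the modified, curved van't
Hoff variant is deliberately out of scope). The predictor is centred at the
harmonic mean temperature Thm = n/Σ(1/T): with this centring 1/Thm is the
arithmetic mean of the 1/T values, so the OLS intercept equals the mean of
ln x3 (asserted at machine precision in the tests) and cov(slope,
intercept) = 0. That independence is the point of the Krug correction — it
lets the enthalpy (from the slope) and the Gibbs energy (from the
intercept) carry uncorrelated standard errors, and makes
sd(TΔS) = sqrt(sd(ΔH)² + sd(ΔG)²) exact rather than an approximation.

**Apparent functions.** ΔsolnH° = −R·m, ΔsolnG° = −R·Thm·a,
ΔsolnS° = (ΔH° − ΔG°)/Thm, all evaluated at Thm. These are *apparent*
functions: saturation mole fractions stand in for activities, so no
activity-coefficient correction is made and the numbers are meaningful for
comparing compositions within a study rather than as absolute equilibrium
constants.

**ζ contributions.** ζH = |ΔH°| / (|ΔH°| + |Thm·ΔS°|). The denominator uses
the *entropic energy term* Thm·ΔS°, not bare ΔS°: a ratio of an enthalpy to
an entropy would mix kJ·mol⁻¹ with J·mol⁻¹·K⁻¹ and is dimensionally
meaningless. Some published statements of this ratio write ΔS° in the
denominator; the tabulated ζ values in the literature are only reproduced
by the TΔS convention, which is what the package implements.

**Mixing decomposition.** ΔmixH° = ΔsolnH° − ΔH_id and likewise for the
entropy, where (ΔH_id, ΔS_id) are the ideal-dissolution functions at Thm —
the hypothetical fusion of the solute into a supercooled liquid. These are
*configuration inputs*: the correct values come from calorimetric
literature for the solute at hand, and the fusion enthalpy measured at the
melting point (packaged for SMT: 33.41 kJ·mol⁻¹ at 468.9 K) is **not** a
valid stand-in at Thm without a ΔCp extrapolation the package does not
attempt. The packaged default for SMT (ΔH_id = 24.84 kJ·mol⁻¹,
ΔS_id = 45.59 J·mol⁻¹·K⁻¹) is back-derived as the composition-averaged
difference between the packaged solution functions and published mixing
functions; it is labelled synthetic in its `source` field and exists so the
decomposition runs out of the box. The decomposition itself is exact
bookkeeping: mixing + ideal reconstructs the solution functions to machine
precision, which is the tested invariant.

**Perlovich sectors.** The printed sector inequalities in the literature
overlap when read literally (e.g. "TΔS > ΔH" covers part of the ΔH < 0
half-plane that other sectors also claim). The implementation is
quadrant-first — the sign pair (ΔH, TΔS) picks the quadrant, the
|ΔH| vs |TΔS| comparison picks the sector within it — which makes the eight
sectors disjoint and exhaustive, matching what the diagrams depict.
Enthalpy-driven sectors are I, IV, V, VIII. Points within `eps`
(default 10⁻⁹ kJ·mol⁻¹) of an axis or of the |ΔH| = |TΔS| diagonal are
classified by the non-strict convention but returned with a `boundary`
flag rather than silently; the origin raises.

**Compensation segmentation.** The ΔH°-vs-ΔG° trajectory is segmented at
the *grid composition* of minimum ΔH° — no spline or interpolation, since
the resolution of the statement is the composition grid itself. The
enthalpy-driven label applies from the start of the grid to the minimum,
entropy-driven from the minimum to the end (Bustamante's criterion). An
equivalent reading segments where the local slope dΔH/dΔG crosses 1; the
two coincide on the packaged data, and the finite-difference slopes are
reported alongside as a diagnostic rather than used for the split.

**Four-point predictor.** ln x3(w1, T) = w1·(A1/T + B1) + w2·(A2/T + B2).
Default fitting is `two_point`: the exact line through the lowest- and
highest-temperature points of each pure solvent, which is the model's
four-measurement selling point and reproduces published coefficient sets
derived the same way. `ols_all` (OLS over all pure-solvent temperatures) is
available for robustness checks. The model is interpolative in both w1 and
T; predictions outside the fitted temperature range trigger a warning, and
are never clamped.

**MRD.** MRD = 100·(1/N)·Σ|x3,exp − x3,calc|/x3,exp. Absolute values (a
mean *deviation* must be non-negative — signed terms would cancel) and
division by N. The calculated-vs-experimental regression (r², adjusted r²,
F, p) is computed on the raw mole-fraction scale, which is what validation
scatter plots in this field show; ln-scale diagnostics are emitted
alongside because r² and especially F are sensitive to that choice.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| gas constant R | 8.314462618 | J·mol⁻¹·K⁻¹ | CODATA value |
| fit weighting | unweighted | — | printed tables report sd for information; the conventional analysis, and the one that reproduces published function tables, is plain OLS |
| predictor fit_mode | two_point | — | the four-point model as designed |
| sector eps | 1e-9 | kJ·mol⁻¹ | numerically zero at the scale of thermodynamic functions (~10 kJ·mol⁻¹) |
| Thm match tolerance (mixing) | 0.5 | K | absorbs printed-Thm rounding (297.6 vs 297.59...) |

A weighted option (1/sd² in ln-space via the delta method) exists but is
off by default; it requires positive sd on every record.

## Synthetic data

`SyntheticSpec` generates tables from the generative inverse of the
analysis model: ln μ(w1, T) = w1(A1/T + B1) + (1 − w1)(A2/T + B2) +
δ·w1(1 − w1), with `n_replicates` multiplicative lognormal draws per grid
point (mean μ, coefficient of variation `noise_cv`) reduced to a mean and
sample sd — the same reduction an experimental table reports. Defaults
mirror the packaged study: the published pure-solvent coefficients, the
21 × 5 %-step composition grid, nine 5 K-step temperatures, three
replicates, and noise_cv = 0.015, the mid-range of the packaged table's
replicate sds (≈1–2% of x3). δ (default 0) is the simplest symmetric
departure from log-linear additivity and exists to probe predictor bias
when the Yalkowsky–Roseman assumption fails.

What the generator deliberately does *not* emulate: temperature-dependent
noise, inter-composition correlation (shared stock solutions,
batch effects), solid-phase transformations during equilibration, or any
curvature of ln x3 in 1/T. Passing recovery tests therefore demonstrate
that the estimation chain is unbiased and correctly calibrated *under the
model's own assumptions* — they do not certify those assumptions for a
given real system; the DSC screen for polymorphism is the experimental
guard the package only records, not replaces.

`recovery_study` (500 simulations at the defaults in the test suite)
checks three calibration properties: |bias(ΔH)| < 0.1 kJ·mol⁻¹, empirical
spread within 25% of the mean propagated SE, and 95% CI coverage (t, n − 2
df) inside [0.90, 0.99]. The study grid for these Monte-Carlo checks is
trimmed to three compositions — the per-composition fits are independent,
so additional compositions only repeat the same check at interpolated
coefficients.

## Numerical conventions and degenerate inputs

- Fits require ≥3 distinct temperatures per composition; duplicate (w1, T)
  grid points, non-positive solubilities, and all-equal temperatures are
  hard errors, not warnings.
- Missing sd columns load as sd = 0 with a logged warning (sd does not
  enter the default unweighted fit).
- Display TSVs round as thermodynamic tables conventionally do (kJ·mol⁻¹
  to 2 decimals, J·mol⁻¹·K⁻¹ to 1, ζ to 3); every writer pairs the display
  file with a full-precision JSON sidecar, and read→write→read round-trips
  are value-identical.
- The analysis pipeline is fully deterministic: re-running on identical
  input and config reproduces machine-readable outputs byte-for-byte.

## Known limitations

- Propagated standard errors on ΔG are small (the intercept is a mean of
  nine points), noticeably smaller than the ± values some published tables
  print for the same quantity; the exact recipe behind such printed ± values
  is typically unstated, so the package reports the transparent first-order
  OLS propagation and treats published ± columns as order-of-magnitude
  context only.
- The F-statistic of the calculated-vs-experimental regression is highly
  sensitive to scale (raw vs ln) and to rounding of the inputs; it is
  reported but should not be used to compare models across studies.
- The apparent functions inherit every limitation of the van't Hoff
  treatment: constant-ΔH assumption over the temperature window, and
  saturation mole fraction as an activity proxy.
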