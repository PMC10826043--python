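# Methods

## Model

All dose–effect analysis rests on the mass-action median-effect equation

    fa / fu = (D / Dm)^m,    fu = 1 − fa,

a reparameterised Hill equation in which `Dm` is the dose producing 50 %
effect (the IC50 in an inhibition assay) and `m` the sigmoidicity coefficient
(`m = 1` hyperbolic, `m > 1` sigmoidal).  Its assumptions: a single, saturable
effect that runs from 0 to 1, monotone in dose, with no baseline offset.  The
equation linearises exactly,

    log10(fa/fu) = m·log10(D) − m·log10(Dm),

so `m` is the slope and `Dm` the antilog of the x-intercept of the
median-effect plot.  Base-10 logarithms are used, matching the classic
median-effect plot convention; the estimates are base-invariant as long as
log and antilog agree.

Interaction between two inhibitors A and B at a shared effect level x is
quantified against Loewe additivity:

    CI  = C_A/IC_x,A + C_B/IC_x,B      (combination index)
    DRI = IC_x(alone) / C(in combination)   per component,

giving the exact identity `CI = 1/DRI_A + 1/DRI_B`.  CI < 1 is synergism,
CI = 1 additivity, CI > 1 antagonism.  The DRI is evaluated at the observed
effect level of each mixture, not only at 50 %; the classic IC50 form is the
special case fa = 0.5.  In the dose-normalized isobologram each observation
is mapped to `(C_A/IC_fa,A, C_B/IC_fa,B)`, whose coordinate sum is the CI, so
a single additive line x + y = 1 serves all effect levels.

## Estimation

`fit_median_effect` is unweighted ordinary least squares on the transformed
variables `(log10 D, log10 fa/fu)`; `r` is the signed Pearson correlation of
those pairs (set to ±1 exactly for a two-point fit).  Points with `fa ∈ {0, 1}`
or `D ≤ 0` have no finite transform; they are excluded with an explicit
warning listing them — never epsilon-nudged, which would silently bias `m`.
Fewer than 2 usable points or a single unique dose is an error; fewer than 4
usable points warns that the fit is poorly constrained.  `m ≤ 0` (effect
falling with dose) constructs with a warning rather than failing, since it is
a legitimate diagnostic of bad data.  No confidence intervals are produced;
the fit is a deterministic transform of the data.

Replicates are aggregated by the arithmetic mean of `fa` per dose (count and
standard deviation retained as metadata).  Aggregation on the `fa` scale
rather than the absorbance scale is a choice, configurable by fitting
unaggregated points instead (`--no-aggregate` on the CLI).

## Combination design and mixture fits

The mixture design is effect-matched, not fixed-ratio: at each target level x
the design pairs each agent's own equi-effective dose, `(IC_x,A, IC_x,B)`, so
the component ratio drifts across levels.  When a mixture series is itself
fitted as a single agent, its "dose" is the arithmetic sum of the component
doses.  With heterogeneous units (mM + mg/mL) that sum is a nominal composite
quantity; the fit carries a composite unit tag and a warning.  This is the
convention under which the reference study's composite rows are reproducible,
and the only self-consistent one available without molar masses for crude
extracts.

Classification is strict by default (any CI < 1 is synergism, matching the
reference analysis); a tolerance band around 1 is available for noisy data.

## Synthetic data

`simulate_dose_effect` draws `y = m·log10(D/Dm) + ε`, `ε ~ N(0, σ²)` per
replicate, then maps back to `fa = 10^y/(1+10^y)`.  Noise on this scale keeps
`fa` strictly inside (0, 1) and makes the OLS fit the exact maximum-likelihood
estimator under the simulation, so parameter-recovery tests are sharp.  A
separate raw-absorbance mode (`simulate_absorbance_readings`) adds Gaussian
noise to instrument readings instead and can push percent inhibition outside
[0, 100], exercising the warning and clamping paths.  What the log-scale
model does **not** emulate: heteroscedastic instrument noise, plate spatial
effects, substrate depletion and DNS chemistry kinetics.  Passing recovery
tests therefore demonstrate correctness of the estimator under its own model,
not robustness to every laboratory artifact.

`simulate_mixture_fa` inverts the CI definition: it returns the fa at which
the dose sum `C_A/IC_fa,A + C_B/IC_fa,B` equals a prescribed `ci_true`
(1 = Loewe-additive null).  For `m > 0` the dose sum is strictly decreasing in
fa, so Brent's method on (10⁻¹², 1 − 10⁻¹²) finds the unique root to
|Δfa| < 10⁻¹⁰; single-agent limits are inverted in closed form.  A bracket
whose signs do not fall from positive to negative (possible only with `m ≤ 0`)
is reported as an error with both endpoint values.

All randomness flows through one `numpy` generator seeded per call; no global
state.

### Calibrated tolerances

The noisy parameter-recovery bound (Dm and m within 10 % of truth) was frozen
after a 1000-seed calibration at the default study-like conditions — true
curve (Dm = 0.061, m = 1.32), 8 log-spaced doses spanning Dm/8 to 8·Dm,
σ = 0.05 on the log10(fa/fu) scale, 3 replicates — where the worst observed
errors were 6.3 % (Dm) and 4.4 % (m).  Mean recovery error is monotone in σ
(checked over 100 seeds at σ = 0, 0.05, 0.2).

## Numerical choices

- Dose ↔ effect transforms are closed-form inverses; the round trip is exact
  to 1e-10 relative and tested as such.
- Percent inhibition outside [0, 100] is retained with a warning (raw data
  preserved); clamping happens only at the conversion to `fa`, where the model
  domain requires it.
- Degenerate controls (positive = negative absorbance) are a hard error that
  names both controls.
- A zero component dose in a mixture is the single-agent limit: CI is still
  defined, the absent component's DRI is reported as `inf`; asking for the
  DRI of the absent component directly is an error.
- Reports render floats at 3 significant figures in CSV/markdown (the
  precision of the reference tables) but at full precision in JSON, whose
  key-sorted output is byte-stable and round-trips losslessly.

## Reproduction limits of the reference values

The bundled reference parameters (`combindex.reference`) are printed to 2–3
significant figures.  Recomputing from them reproduces every reference CI to
±0.01 and every DRI to ±0.02, and the acarbose+kaempferol composite fit to
within 2 % — but individual equi-effective dose entries can deviate by a few
units in their last printed digit (worst case ≈1 % relative, 0.352 vs 0.348
at the 90 % level), because the original analysis used unrounded parameters
and unrounded observed effects.  The reference acarbose+propolis composite
row is not recomputable from printed values at all (Dm ≈ 0.308 recomputed vs
0.274 reported, m within ~3 %) and is excluded from reproduction tests; the
very shallow propolis curve (m ≈ 0.51) amplifies rounding of the inputs into
large dose-scale differences.

## Known limitations

- Binary combinations only; no Bliss independence, ZIP, HSA or
  response-surface models.
- No uncertainty quantification on fits or CI (no bootstrap); `r` is the only
  goodness-of-fit diagnostic, as in the classic median-effect workflow.
- No plate-layout parsing, kinetic assay modes or instrument file formats;
  input is tidy CSV.
- Isobologram and fa–CI operations return plot-ready data structures; no
  figures are rendered.
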