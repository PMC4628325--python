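# Methods

## The model

`volratio` treats a pair of tumour-volume measurements — `X1` at a
reference CT timepoint and `X2` at follow-up — as independent random
variables with means `μ1, μ2`, standard deviations `σ1, σ2`, coefficients
of variation `c_i = σ_i/μ_i` and correlation `ρ`. Classifying disease
course from the relative change `(X2 − X1)/X1` is equivalent to inference
on the ratio `W = X2/X1`. Assuming `(X1, X2)` approximately bivariate
normal, the Geary–Hinkley transformation

    Z = (W·μ1 − μ2) / sqrt(σ2² − 2·W·ρ·σ1·σ2 + W²·σ1²)

is approximately standard normal; the approximation is considered reliable
for CVs roughly inside (0.005, 0.39), and the package warns (never blocks)
outside that range. Inverting the transformation gives confidence limits
for `μ2/μ1`:

    Lower, Upper = (X2/X1) · (1 − t²ρc1c2 ∓ t·√(c2² − 2ρc1c2 + c1² − t²c1²c2²(1−ρ²))) / (1 − t²c2²)

valid when `t·c2 < 1` (`t` the two-sided normal quantile of the level; we
use the conventional 1.96 literally at 95%, the exact quantile otherwise).

With independent errors and a constant CV (`ρ = 0`, `c1 = c2 = k`) the
limits simplify, and the critical ratios of the "no change" test
(`H0: μ1 = μ2`) become

    w_L, w_U = (1 ∓ t·√(2k² − t²k⁴)) / (1 − t²k²)

These satisfy `w_L · w_U = 1` exactly: the decision band is a single
multiplicative factor, `×w_U` up and `÷w_U` down.

## Defaults and units

- `k = 0.3/1.96 ≈ 0.1531`: the measurement CV of CT lung-lesion volumetry,
  i.e. a 95% repeatability half-width of 30%, commonly summarized as a
  ~15% standard deviation of repeated measurements. Every formula takes
  `k` explicitly; 0.05 and 0.10 reproduce the documented sensitivity
  analysis.
- Level 0.95, `t = 1.96` (literal, see above).
- Volumes in cm³, effective diameters in mm, probabilities as fractions
  internally; percents appear only in presentation fields.

At the defaults, `w_L = 0.64329`, `w_U = 1.55451`: a measured volume must
fall below ~0.64× or above ~1.55× of its reference before the change is
distinguishable from measurement noise at the 95% level.

## Rounding convention for reported thresholds

The integer percent pair exploits the band's exact reciprocity: the upper
percent is `round(100·(w_U − 1))` (half away from zero) and the lower
percent is the change of the *exact reciprocal of that rounded upper*,
`round(100·(1/(1 + upper/100) − 1))`. So at the default CV the pair is
(−35%, +55%) — a ×1.55 increase and its reciprocal ÷1.55 decrease — and at
`k = 0.05` it is (−13%, +15%). Rounding the lower critical ratio's own
percent change (−35.67%) would instead print −36% and break the
reciprocal reading of the pair; published threshold pairs for this model
follow the reciprocal convention, which we therefore adopt. All statistics
(p-values, power, rejection regions) use the unrounded critical ratios;
the rounded percents are for reporting and clinical classification, where
a change exactly on a threshold counts as stable (non-rejection).

## p-value and power

Under the null the transformation reduces to
`z0 = (w − 1)/(k·√(1 + w²))`, giving the two-sided
`p = 2(1 − Φ(|z0|))`; `p` equals the nominal α at the unrounded critical
ratios. Power at a true ratio `r` evaluates the same transformation with
`μ2 = r·μ1`:

    power(r) = Φ(z(w_L; r)) + 1 − Φ(z(w_U; r)),   z(w; r) = (w − r)/(k·√(r² + w²))

At the defaults this gives 87.5% at a 50% decrease, 16.2% at a 20%
decrease, 20.7% at a 30% increase, 75.0% at an 80% increase, ~50% at the
thresholds themselves, and 5.0% (the size) at `r = 1`. For normal errors
these values are essentially exact, not approximate: `P(X2/X1 ≤ w)`
equals `Φ(z(w))` up to the negligible probability (~3·10⁻¹¹ at the
default CV) of a non-positive baseline draw.

## Monte Carlo validation

`mc_validation` draws independent pairs with means `μ1` and `r·μ1` and SD
`k·mean` under three error families, all moment-matched to mean `μ` and
SD `k·μ`:

- **normal** — `N(μ, (kμ)²)`; baselines ≤ 0 are resampled so the ratio is
  defined (practically never triggered at the default CV);
- **lognormal** — log-scale variance `ln(1 + k²)`, log-mean
  `ln μ − ½·ln(1 + k²)` (the only parameterization preserving the stated
  mean/SD relation);
- **uniform** — on `μ(1 ± √3·k)`; a thin-tailed stand-in for segmentation
  error with bounded support.

Rejection counts use the **unrounded** critical ratios by default
(`boundaries="exact"`), matching the statistical test; `"rounded"` applies
the integer-percent band instead. The distinction only matters when the
true ratio sits on a boundary: at `r = 0.65` the exact boundary gives an
expected rate of ~48%, whereas the rounded 0.65 boundary gives exactly 50%
by symmetry. Each (model, ratio) cell draws from its own child stream of a
single `SeedSequence`, so runs are reproducible and cells independent.

At `n = 10,000` (the study size used throughout, comfortably fast on one
CPU) the normal model reproduces the analytic power at every default
ratio; the lognormal model's type I error drops to ~4% (its ratio
distribution is exactly lognormal, slightly lighter in the rejection
tails than the normal approximation), and the uniform model's to ~3.3%.
The thin-tailed uniform stand-in is the weakest emulation: distributions
labelled "empirical" in validation studies can be heavier-tailed than any
SD-matched uniform, so only the order of magnitude of its rates is
meaningful.

## Effective-diameter mapping

The effective diameter is the diameter of the volume-equivalent sphere,
`d = 2·(3V/4π)^(1/3)`; relative changes map between scales by
cube-rooting/cubing the ratio. The reported diameter thresholds convert
the *rounded* volume pair (0.65, 1.55), giving (−13%, +16%) — a strictly
narrower stable region than the one-dimensional RECIST (−30%, +20%).
Conversely, cubing the RECIST pair gives −65.7% and +72.8% in volume; the
package prints the half-away roundings (−66%, +73%), and tests accept a
±1 pp discrepancy against sources that truncate −65.7 to −65.

## Multi-reader response pipeline

`response_pipeline` consumes tidy per-reader measurement tables
(`patient_id, lesion_id, timepoint_index, reader_id, volume_cm3`). For
each reader's series it computes relative changes against baseline
(timepoint 0) and against the nadir (that reader's minimum over strictly
earlier timepoints — per reader, not consensus, so each series is
self-contained), classifies each change as PR/SD/PD with the rounded
thresholds, and reports both reference modes ("two-way" evaluation, which
balances responding and progressive assessments).

Reader agreement is tested against the band the model predicts from the
measurement CV alone: within each (patient, lesion, timepoint, reference)
group with ≥2 readers, the band `[(1+m)·w_L − 1, (1+m)·w_U − 1]` is
anchored at the group-mean change `m` and each reader's change is tested
for membership; the overall within-band fraction carries an exact
Clopper–Pearson binomial CI.

Two anchorings are available, and they answer different questions:

- **leave-in** (default): `m` includes the reader under test. Because each
  reader then sits partly inside its own anchor, per-assessment coverage
  exceeds the nominal level — with 6 readers the reader-minus-mean scatter
  is √(5/6) of a full ratio's, pushing coverage to ~97% — which is the
  construction under which multi-reader clinical validations report
  within-band fractions around 97%.
- **leave-one-out** (`leave_one_out=True`): the reader is tested against
  the other readers' consensus; measured coverage on synthetic cohorts is
  ~94–95%, i.e. the construction whose nominal level the 95% CI actually
  describes. Calibration tests use this mode.

## Synthetic cohort generator

`synthetic_cohort` emulates the structure of a multi-reader NSCLC
follow-up validation: 10 patients, one preselected lung target lesion
each, 7 timepoints (baseline + 6 follow-ups, ~70 assessed timepoints),
6 readers reading every scan — ~420 measurements per cohort. Baseline
volumes are log-uniform on [0.195, 380.976] cm³ (the documented clinical
size span); each patient follows one of four courses cycled
deterministically (responding ×0.75/step, progressing ×1.35/step, stable,
respond-then-relapse), with mild lognormal biological wobble
(`sd_log = 0.05`) so the responding/progressive split is roughly balanced
under two-way evaluation. Observed volumes multiply the truth by an
independent lognormal reader error with CV `k` (moment-matched as in the
simulator), keeping volumes positive across the full size range.

What the generator does *not* emulate: scanner/protocol heterogeneity,
slice-thickness effects, reader-specific bias or correlated reader error,
lesion-size-dependent CVs, and new or disappearing lesions. Passing
calibration tests therefore show that the pipeline and band construction
are correct under the model's own assumptions — not that a specific
clinical dataset satisfies those assumptions.

## Numerical choices and degenerate inputs

- Thresholds exist only for `t·k < 1`; `t·c2 ≥ 1` raises with the violated
  condition named. Zero CVs give the degenerate point interval.
- Band membership allows a few-ulp tolerance so the `k = 0` band contains
  its own anchor despite floating-point averaging.
- Percent rounding is half-away-from-zero everywhere except the
  reciprocal-pair convention above.
- Groups with a single reader are excluded from agreement (warning);
  series without a baseline raise with their identifiers listed.
- Monte Carlo scale invariance is exact by construction: draws are formed
  as `μ·(unit-mean deviate)`, so rates at fixed seed do not depend on μ1.

## Known limitations

- The model is first-order: it ignores any dependence of the CV on lesion
  size and assumes uncorrelated errors between timepoints (`ρ` is exposed
  in the CI but defaults to 0 and is not simulated).
- The uniform error family is an interpretation; bounded, thin-tailed.
- The agreement band anchors on the arithmetic group mean; with lognormal
  errors the mean slightly exceeds the median, adding ~0.5 pp of coverage.
- Multi-lesion RECIST bookkeeping (target sums, new lesions, confirmation
  rules) is out of scope; one lesion per series is assumed well-defined.
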