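# volratio

Decision thresholds and reliability checks for CT tumour volumetry, built
on the Geary–Hinkley model of the ratio of two measurements.

## The problem

RECIST-style response assessment classifies a tumour's course (partial
response / stable disease / progressive disease) by thresholding its
relative change between scans. For one-dimensional diameters the
thresholds are standardized (−30%, +20%); for **volumes** they are not.
`volratio` derives volume thresholds from first principles: given the
repeatability of the measurement itself (a coefficient of variation `k`,
~15% for semi-automated lung-lesion volumetry on CT), how large must an
observed change be before it is distinguishable from measurement noise?

It is aimed at quantitative-imaging researchers and trial methodologists
who need defensible volumetric response criteria, want to stress-test them
by simulation, or need to check whether a panel of readers scatters no
more than the measurement model predicts.

## The model

Measurements `X1, X2` at two timepoints are treated as independent
normals with constant CV (`σ_i = k·μ_i`). The Geary–Hinkley
transformation of the ratio `W = X2/X1`,

    Z = (W·μ1 − μ2) / sqrt(σ2² − 2Wρσ1σ2 + W²σ1²),

is approximately standard normal, which yields a confidence interval for
`μ2/μ1` and, for the no-change null, critical ratios

    w_L, w_U = (1 ∓ t·sqrt(2k² − t²k⁴)) / (1 − t²k²),   w_L·w_U = 1.

At `k = 0.3/1.96` and the 95% level this gives `w_L ≈ 0.64`,
`w_U ≈ 1.55`: **−35% volume decrease ⇒ PR, +55% increase ⇒ PD, anything
between ⇒ SD.** The package also computes p-values and power for the
no-change test, validates the thresholds by Monte Carlo under normal,
lognormal and uniform error models, converts thresholds to the
effective-diameter scale, classifies longitudinal multi-reader cohorts,
and ships a synthetic-cohort generator so every pipeline is testable
without patient data. See `docs/methods.md` for the full account.

## Worked example

```python
>>> import volratio as vr
>>> ts = vr.symmetric_thresholds(vr.DEFAULT_CV)          # k = 0.3/1.96
>>> ts.lower_ratio, ts.upper_ratio
(0.6432876386455412, 1.5545145591566565)
>>> ts.lower_pct, ts.upper_pct
(-35, 55)
>>> round(100 * vr.power_at_ratio(0.5, vr.DEFAULT_CV, ts), 1)
87.5
>>> vr.pvalue_no_change(0.58, vr.DEFAULT_CV)
0.017613447969750277
>>> vr.classify_change(0.58, ts)
'decrease'
```

A true halving of volume is detected with 87.5% power; an observed ratio
of 0.58 (−42%) is a significant decrease (p ≈ 0.018), i.e. a partial
response. The same numbers are available from the shell:

```sh
$ volratio thresholds --k 0.15306
{ "lower_pct": -35, "upper_pct": 55, ... }
$ volratio simulate --model normal --n 10000 --seed 1 -o study.csv
$ volratio generate --seed 1 -o cohort.csv
$ volratio classify cohort.csv
{ "n_assessments": 720, "fraction_within": 0.975, ... }
$ volratio extrapolate --k 0.15306 --recist
{ "diameter_thresholds": {"lower_pct": -13, "upper_pct": 16, ...},
  "recist_volume_thresholds": {"lower_pct": -66, "upper_pct": 73} }
```

The last command shows the volume thresholds restated for effective
diameters (−13%, +16% — strictly inside RECIST's −30%, +20%) and,
conversely, RECIST's diameter thresholds cubed onto the volume scale.

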