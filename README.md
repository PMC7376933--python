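# flexchart

Centile reference charts for monitoring recovery of knee flexion after
total knee arthroplasty (TKA).

## The problem

After a knee replacement, clinicians track a patient's knee flexion
active range of motion (AROM, in degrees) across rehabilitation visits,
but protocols describe only the *average* recovery course. A reference
chart — a fan of centile curves of flexion against days post-surgery,
analogous to a pediatric growth chart — lets a clinician place an
individual measurement in the distribution of comparable patients: a
reading below the 5th centile flags an unusually slow recovery, one near
the 90th an unusually fast one.

`flexchart` builds and validates such charts from long-format clinical
data (patient id, surgery date, day post-op, flexion), and ships a
synthetic cohort generator with known ground-truth centiles so the whole
pipeline is testable without access to clinical records.

## The model

Flexion at `t` days post-surgery is modelled with distributional
(GAMLSS-style) regression: every parameter of the response distribution
is a smooth function of transformed time `x = t^p`. Six candidate
families of increasing complexity are supported — NO, GA (median and
scale), TF, BCCG (plus skewness), BCT, BCPE (plus kurtosis). The
workhorse is the Box-Cox Cole–Green (LMS) family

    z = ((y / μ(x))^ν − 1) / (ν σ(x)),    z ~ N(0, 1) truncated to y > 0,

whose `μ` is the median curve, `σ` a relative scale and `ν` a skewness
power. `μ` and `σ` are penalized natural cubic smoothing splines whose
flexibility is expressed as effective degrees of freedom (edf — the trace
of the smoother matrix, so fractional values are meaningful); `ν` and any
kurtosis parameter default to constants. Fitting is penalized maximum
likelihood by RS-type backfitting with step-halving, so the deviance
trace is non-increasing.

Model development follows the reference-chart playbook: fit all candidate
families; compare by the Schwarz Bayesian Criterion
`SBC = deviance + df·log(n)`, mean squared error under patient-level
5-fold cross-validation, and centile coverage (the fraction of
observations below each curve, which should match the nominal level);
prefer the least complex model among near-ties. Validation is temporal:
the chart is built on the earlier ~75% of measurements (by surgery date)
and assessed on the later ~25% with per-centile z-tests for proportions
and the average bias (mean observed − predicted median).

## Worked example

```python
import numpy as np
from flexchart import (GeneratorConfig, generate_cohort, temporal_split,
                       ModelSpec, fit_gamlss, build_chart, validate_model, sbc)

cohort = generate_cohort(GeneratorConfig(n_patients=500, seed=7))
dev, test = temporal_split(cohort, fraction=0.75)

spec = ModelSpec(family="BCCG", time_power=0.56, df_mu=2.2, df_sigma=1.2)
model = fit_gamlss(dev, spec)
chart = build_chart(model)                 # integer days 2..120 × 7 centiles
report = validate_model(model, test)       # later-surgery patients only
```

prints (abridged):

```
development: 1234 obs / 368 patients; test: 409 obs / 132 patients
BCCG fit: deviance 10174.4, df 8.4, SBC 10234.2
day   7: 5th   60.1  25th   78.4  median   89.2  75th   99.1  95th  111.9
day  30: 5th   74.7  25th   93.2  median  104.4  75th  114.7  95th  128.3
day  90: 5th   91.6  25th  105.7  median  114.6  75th  123.0  95th  134.2
 level  expected_pct  observed_pct   n      z     p
  0.05           5.0         2.934 409 -1.917 0.055
  0.50          50.0        51.589 409  0.643 0.520
  0.95          95.0        95.355 409  0.329 0.742
average bias: -0.79 degrees
```

Reading: the fitted median rises from ~89° one week after surgery to
~115° at three months with the interquartile band roughly 15–20° wide;
on the held-out later-surgery patients every observed coverage
proportion is statistically compatible with its nominal level and the
chart's median over- or under-predicts by under a degree on average.

The same pipeline is available from the shell:

```bash
flexchart simulate --n-patients 500 --seed 7 --out cohort.csv
flexchart run --seed 7 --out results/        # simulate → split → select → chart → validate
flexchart validate --model results/model.json --input results/test.csv --out report.json
```

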