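# aeemax

Nonexercise estimation of maximal oxygen uptake (VO₂max, mL/kg/min) from
free-living wrist-tracker data.

Cardiorespiratory fitness is normally measured with a maximal graded
exercise test — expensive, exhausting, and unsuitable for routine
monitoring. This package implements an alternative for anyone with a few
days of minute-level heart-rate and activity data from a watch-type fitness
tracker: exercise physiologists, epidemiologists working with wearable
cohorts, and developers of fitness applications.

## Method

From each subject's minute-resolution trace of heart rate (HR, beats/min)
and activity energy expenditure (aEE, kcal/kg/h), the pipeline

1. applies a centered moving-average filter to both signals (within
   contiguous wear segments; non-wear minutes are never imputed),
2. keeps only minutes at which both smoothed signals *increased* — periods
   of genuine physical exertion,
3. keeps only minutes with HR > 120 beats/min, where the HR–aEE
   relationship is approximately linear,
4. fits the per-subject ordinary least-squares line aEE = *slope*·HR + b,
5. extrapolates it to the predicted maximal heart rate
   (HRmax = 200 − 0.67·age for women, 216 − 0.93·age for men).

The aEE value of the line at HRmax is **aEEmax** — the subject's projected
energy expenditure at maximal effort — and together with the line's
**slope** it feeds a six-covariate linear model:

    VO₂max = 63.262 + 0.027·aEEmax − 1.776·slope − 0.242·%fat
             − 0.150·age + 3.264·sex − 0.09·height        (sex: F=0, M=1)

A trace qualifies only with ≥ 900 minutes (15 h) of valid wear time.
Model fits are reported with R, R², SEE, and the PRESS leave-one-out
cross-validated R_P and SEE_P (computed in closed form from the hat
matrix), plus a subgroup constant-error (CE) validation by sex, age group
and VO₂max level. A seeded simulator generates cohorts and traces with
known ground truth for end-to-end testing.

## Worked example

```python
from aeemax import published_model

model = published_model()
estimate = model.predict(dict(
    aeemax=141.0,            # kcal/kg/h, extracted from the trace
    slope=1.10,              # kcal/kg/h per bpm
    percent_body_fat=20.4,
    age=27, sex="male", height=174.3,
))
print(f"{estimate:.3f}")     # -> 43.706
```

43.706 mL/kg/min is the estimated VO₂max for a 27-year-old man of average
build and fitness for his group — comparable to that group's typical
measured value (~42 mL/kg/min). `model.summary()` prints the coefficient
table with the reported metrics (R 0.807, SEE 3.518, R_P 0.787,
SEE_P 3.667 on the n=191 development cohort).

Fitting your own cohort:

```python
from aeemax import VO2maxModel, extract_features, read_trace, read_cohort, cohort_frame

profiles = read_cohort("cohort.csv")
features = [extract_features(read_trace(f"traces/{p.subject_id}.csv"), p)
            for p in profiles]
results = VO2maxModel.from_features(features, profiles).fit()
print(results.summary())
report = results.subgroup_validation()      # CE/SD per subgroup
```

The same steps are available from the shell via the `aeemax` console
script (`simulate`, `extract`, `fit`, `predict`, `validate` subcommands).

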