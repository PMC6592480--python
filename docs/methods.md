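# Methods

## The estimation problem

Maximal oxygen uptake (VO₂max, mL/kg/min) is the criterion measure of
cardiorespiratory fitness, normally obtained with a maximal graded exercise
test and respiratory gas analysis. This package estimates it without any
exercise protocol, from 3 days of free-living, minute-resolution
heart-rate (HR) and activity-energy-expenditure (aEE) data as produced by
watch-type trackers, together with basic anthropometrics.

The physiological premise is that during sustained exertion (HR above
roughly 120 beats/min) aEE rises approximately linearly with HR, and that
the *trend* of that relationship — not the accuracy of any single sensor
reading — carries the fitness signal. Two per-subject features summarise
it: the OLS **slope** of aEE on HR (kcal/kg/h per beat/min) over the
selected high-exertion minutes, and **aEEmax**, the value of that line at
the age- and sex-predicted maximal heart rate. Because both features are
fitted trends over hundreds of minutes, systematic device bias largely
cancels; this is why consumer-grade trackers suffice.

## Signal-processing chain

1. **Wear segmentation.** A minute is "worn" iff both HR and aEE are
   present. Contiguous wear runs at consecutive minute timestamps form
   segments; smoothing windows and first differences never cross a segment
   boundary, because a difference across a device-off gap is meaningless.
2. **Smoothing.** Centered moving average, default window 5 min (odd,
   configurable), shrinking to the available points at segment edges. Five
   minutes suppresses beat-to-beat and quantisation noise while preserving
   activity bouts at 1-min sampling.
3. **Co-increase selection.** Keep minute *t* iff both smoothed signals
   strictly increased from *t−1* (within a segment). The later endpoint of
   the increasing step is the selected minute. Strictness matters: a flat
   step is not exertion.
4. **HR gate.** Keep selected minutes with smoothed HR strictly
   > 120 beats/min (configurable). Below this the HR–aEE relationship is
   nonlinear and would bias the fitted line. The gate is applied after
   co-increase selection; both orders yield the same set since the
   operations commute (each is a per-minute predicate), so the chain order
   is presentational.
5. **Sufficiency.** At least 900 valid wear minutes (15 h) are required;
   a calendar span under 3 days warns but does not fail, since total
   information content, not span, drives the fit.
6. **Per-subject fit.** OLS of smoothed aEE on smoothed HR over the
   selected minutes (at least 30 points, configurable; two-parameter OLS on
   fewer high-autocorrelation points is unstable). Predicted
   HRmax = 200 − 0.67·age (women) or 216 − 0.93·age (men); aEEmax =
   slope·HRmax + intercept. A negative or sub-resting aEEmax
   (< 1 kcal/kg/h) is flagged, not dropped — exclusion policy belongs to
   the analyst.

## The VO₂max model

OLS of measured VO₂max on {aEEmax, slope, percent body fat, age,
sex (F=0/M=1), height}, with intercept — 7 parameters. Reported metrics:

- R: Pearson correlation of measured vs fitted; R² its square; adjusted R²
  is reported separately (the two are easily conflated in this literature).
- SEE = √(SSE/(n−7)), the residual-degrees-of-freedom convention.
- PRESS = Σᵢ (eᵢ/(1−hᵢᵢ))², the sum of squared leave-one-out prediction
  errors, computed in closed form from the hat diagonal (exactly equal to
  refitting n times; a unit leverage makes the left-out prediction
  undefined and is reported as an error naming the case).
- R_P = √(max(0, 1 − PRESS/SS)) with SS the total sum of squares;
  SEE_P = √(PRESS/n) by default, √(PRESS/(n−7)) via argument — the n
  convention treats each leave-one-out error as an honest out-of-sample
  residual. PRESS ≥ SSE always, hence SEE_P ≥ SEE and R_P ≤ R.
- Standardised coefficients (betas): coefficient × sd(x)/sd(y).

The `published_model()` coefficients (63.262, 0.027, −1.776, −0.242,
−0.150, 3.264, −0.09) and their metrics are reported values from the
model's n=191 development cohort, carried as constants for out-of-the-box
prediction; that cohort is not public, so those metrics are never
recomputed here.

**Subgroup constant error.** CE = mean(measured − estimated) per subgroup,
with SD of the same differences, for sex, age (≤/> cut) and measured
VO₂max level (≤/> cut); cuts default to cohort medians and can be set to
the conventional 40 years / 36 mL/kg/min. When the model is evaluated on
its own training cohort, OLS orthogonality forces whole-sample CE and the
CE of every included categorical covariate's levels (sex) to zero at
machine precision; the high-fitness group shows positive CE and the
low-fitness group negative CE — regression to the mean, a property of any
least-squares fit, not a defect.

## Simulator

The simulator provides ground truth the real study cannot: the latent
slope and aEEmax of every subject.

**Cohort.** Six groups (2 sexes × age bands 20–35/36–50/51–65) with the
development cohort's group sizes (34/26/30 men, 36/35/30 women; n=191) and
group means/SDs for height, weight, percent fat, aEEmax and slope.
Covariates are drawn from independent normals truncated at ±3 SD
(physiological plausibility with near-normal moments); age is uniform on
its band. Measured VO₂max is the generative linear model (default: the
published coefficients) on the *true* covariates plus N(0, 3.5) noise —
3.5 mL/kg/min matching the scale of the reported SEE.

**Traces.** Per day: a 14-h wear window (07:00–21:00), overnight non-wear,
one 15-min "shower" gap at a random position, and 4 activity bouts placed
in non-overlapping slots. A bout ramps HR at 5 bpm/min from rest
(uniform 58–72 bpm) to a peak at 75–95% of the subject's HRmax, holds an
interval-style sustained phase (oscillations of up to 25 bpm, kept above
125 bpm), and ramps down. The latent response is aEE = slope·HR + b for
HR ≥ 105 bpm and a saturating quadratic joining (rest, 1 kcal/kg/h) to the
line at 105 bpm below it — reproducing the low-HR nonlinearity that makes
the 120-bpm gate necessary. Observed HR and aEE add independent Gaussian
sensor noise (defaults 2.0 bpm and 2.0 kcal/kg/h — minute-averaged
wrist-PPG HR error and ~1.5% of a typical maximal aEE).

The 105-bpm knee is a deliberate geometric choice: any minute passing the
120-bpm gate has a 5-min smoothing window whose raw samples lie at most
2 × 5 bpm/min = 10 bpm lower, i.e. entirely in the linear regime. Since
averaging commutes with an affine response, noiseless selected points lie
*exactly* on the true line and the pipeline recovers slope, intercept and
aEEmax to machine precision — the noiseless recovery tests check an exact
identity, not an approximation. Under default noise, slope recovery error
is dominated by correlated post-smoothing noise and HR
errors-in-variables attenuation (≈1.5% SD, ≲0.5% bias); slope and aEEmax
are within 5% relative of truth for ≈99 of 100 simulated subjects.

All draws flow from one explicit seed; identical configuration and seed
give bit-identical cohorts and traces.

**What the simulator does not emulate** — and hence what passing tests do
not demonstrate about real data: circadian HR structure, HR recovery
kinetics, device-specific bias and quantisation, aEE noise that scales
with intensity, correlated covariates within groups (e.g. the empirical
aEEmax–slope correlation), real bout intensity/duration distributions, and
any deviation from within-subject HR–aEE linearity above the gate. The
recovery and coefficient-recovery results validate the *pipeline's
correctness under its own model assumptions*, not the physiological model
itself.

## Numerical and design notes

- Strict inequalities for co-increase and the HR gate ("increased",
  "greater than").
- Regression direction is aEE on HR: the slope's units (kcal/kg/h per bpm)
  and the definition of aEEmax as an aEE value at a given HR require it.
- Per-subject regressions pool all days; no per-day structure is imposed.
- HRmax is used unrounded.
- Sex coding female=0/male=1 makes the sex coefficient positive, matching
  the higher male VO₂max.
- Missing minutes are never imputed; rows with blank cells simply fail the
  wear mask.
- Problem sizes in tests and the acceptance script: the default n=191
  cohort for end-to-end runs, 100 seeds for the two recovery experiments,
  designs of n=12–50 for the PRESS equivalence check — enough for each
  check's statistical power while keeping the whole suite to a few seconds.
- Coefficient recovery (each of 7 coefficients within 3 SE) has joint
  coverage ≈98% per cohort; over 100 seeds the observed pass count
  fluctuates binomially around 98, occasionally as low as ~93 for an
  unlucky seed family.

## Limitations

- The published model applies to healthy adults 20–65; extrapolation
  beyond that range inherits the HRmax formulas' error.
- Subjects with predicted HRmax near or below the 120-bpm gate (very old
  ages) make the aEEmax construction degenerate; the pipeline flags this.
- Free-living subjects who never exceed 120 bpm yield no regression points
  and are excluded by design, as in the original protocol.
- CE validation on the training cohort is an internal-consistency check;
  external validity requires an independent cohort.
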