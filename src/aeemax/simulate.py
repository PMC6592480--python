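"""Synthetic cohort and trace generator with known ground truth.

Emulates a study cohort of six groups (two sexes x three age bands,
20-35 / 36-50 / 51-65 years) whose anthropometrics and fitness features are
drawn from the published group means and SDs, and 3-day minute-resolution
wrist-tracker traces for each subject. Each subject has a latent linear
heart-rate -> activity-energy-expenditure response above ~105 bpm (slope and
aEEmax are the ground truth the extraction pipeline must recover) and a
deliberately saturating, nonlinear response at lower heart rates — the
failure mode that motivates the 120 bpm gate. Non-wear gaps (overnight
sleep, a daily shower) break the trace into wear segments.

Every random draw flows from one explicit seed: identical configuration and
seed reproduce bit-identical cohorts and traces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParameterError
from .io import ActivityTrace, SubjectProfile
from .regression import COVARIATES, PUBLISHED_COEFFICIENTS

#: Cohort group parameters: mean (sd) of each covariate per sex x age band,
#: and the group sizes, matching the published development cohort (n=191).
GROUP_DEFAULTS = {
    "male_20_35": dict(n=34, age_range=(20, 35), height=(174.3, 5.6), weight=(73.9, 8.0),
                       percent_body_fat=(20.4, 5.2), aeemax=(141.0, 14.6),
                       slope=(1.10, 0.14), vo2max=(42.3, 3.6)),
    "male_36_50": dict(n=26, age_range=(36, 50), height=(172.6, 6.1), weight=(74.7, 9.7),
                       percent_body_fat=(24.8, 4.9), aeemax=(123.7, 15.1),
                       slope=(1.04, 0.13), vo2max=(39.9, 3.5)),
    "male_51_65": dict(n=30, age_range=(51, 65), height=(167.1, 4.9), weight=(67.0, 6.1),
                       percent_body_fat=(24.2, 5.1), aeemax=(111.2, 11.0),
                       slope=(1.04, 0.12), vo2max=(38.1, 4.6)),
    "female_20_35": dict(n=36, age_range=(20, 35), height=(161.9, 5.4), weight=(55.8, 7.3),
                         percent_body_fat=(29.4, 6.7), aeemax=(112.5, 15.8),
                         slope=(0.92, 0.17), vo2max=(35.3, 3.5)),
    "female_36_50": dict(n=35, age_range=(36, 50), height=(160.0, 5.2), weight=(60.6, 6.1),
                         percent_body_fat=(33.9, 4.9), aeemax=(107.7, 12.1),
                         slope=(0.98, 0.14), vo2max=(31.4, 4.1)),
    "female_51_65": dict(n=30, age_range=(51, 65), height=(155.3, 4.8), weight=(56.2, 6.1),
                         percent_body_fat=(33.8, 5.4), aeemax=(102.0, 10.3),
                         slope=(0.96, 0.13), vo2max=(30.5, 3.9)),
}

REST_AEE = 1.0          # resting activity energy expenditure, kcal/kg/h (1 MET)
LINEAR_KNEE_BPM = 105.0  # below this the HR->aEE response saturates (nonlinear)
RAMP_BPM_PER_MIN = 5.0   # heart-rate ramp rate during activity bouts
SHOWER_GAP_MIN = 15
TRACE_START = "2024-01-06 00:00"


@dataclass
class SimConfig:
    """All simulator knobs. ``seed`` is mandatory — no implicit entropy.

    ``n_per_group=None`` keeps the per-group sizes of the development cohort
    (34/26/30 men, 36/35/30 women). Noise SDs: ``hr_noise_sd`` in beats/min,
    ``aee_noise_sd`` in kcal/kg/h (per-minute sensor noise),
    ``vo2max_noise_sd`` in mL/kg/min (residual SD of the generative model).
    """

    seed: int
    n_per_group: int | None = None
    group_params: dict = field(default_factory=lambda: {k: dict(v) for k, v in GROUP_DEFAULTS.items()})
    days: int = 3
    wear_hours_per_day: float = 14.0
    wear_start_hour: int = 7
    bout_rate: int = 4
    hr_noise_sd: float = 2.0
    aee_noise_sd: float = 2.0
    vo2max_noise_sd: float = 3.5
    resting_hr_range: tuple = (58.0, 72.0)
    peak_hr_fraction: tuple = (0.75, 0.95)
    vo2max_coefficients: dict = field(default_factory=lambda: dict(PUBLISHED_COEFFICIENTS))
    truncate_sd: float = 3.0

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("seed is required")
        for name in ("hr_noise_sd", "aee_noise_sd", "vo2max_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.n_per_group is not None and self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        if self.days < 1:
            raise ParameterError("days must be >= 1")
        self.resting_hr_range = tuple(self.resting_hr_range)
        self.peak_hr_fraction = tuple(self.peak_hr_fraction)
        for gp in self.group_params.values():
            for key, val in gp.items():
                if isinstance(val, (list, tuple)):
                    gp[key] = tuple(val)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["resting_hr_range"] = list(self.resting_hr_range)
        d["peak_hr_fraction"] = list(self.peak_hr_fraction)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        for key in ("resting_hr_range", "peak_hr_fraction"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent per-subject quantities the pipeline is meant to recover.

    ``true_aeemax = true_slope * true_hrmax + true_intercept`` exactly.
    """

    subject_id: str
    group: str
    true_slope: float
    true_intercept: float
    true_aeemax: float
    true_hrmax: float
    true_vo2max: float
    resting_hr: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _trunc_normal(rng, mean, sd, n_sd):
    """Normal draw rejected outside mean +/- n_sd * sd (keeps moments near-normal)."""
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sd * sd:
            return x


def _hrmax(age, sex):
    return 200.0 - 0.67 * age if sex == "female" else 216.0 - 0.93 * age


def simulate_cohort(config: SimConfig, rng=None):
    """Draw subject profiles and their ground truth.

    Covariates are truncated-normal within each group; measured VO2max is
    the generative linear combination of the (true) covariates plus
    N(0, vo2max_noise_sd) noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    coefs = config.vo2max_coefficients
    profiles, truths = [], []
    k = 0
    for group, gp in config.group_params.items():
        sex = "female" if group.startswith("female") else "male"
        n = config.n_per_group if config.n_per_group is not None else gp["n"]
        lo_age, hi_age = gp["age_range"]
        for _ in range(n):
            k += 1
            sid = f"S{k:04d}"
            age = int(rng.integers(lo_age, hi_age + 1))
            height = _trunc_normal(rng, *gp["height"], config.truncate_sd)
            weight = _trunc_normal(rng, *gp["weight"], config.truncate_sd)
            fat = _trunc_normal(rng, *gp["percent_body_fat"], config.truncate_sd)
            aeemax = _trunc_normal(rng, *gp["aeemax"], config.truncate_sd)
            slope = _trunc_normal(rng, *gp["slope"], config.truncate_sd)
            hrmax = _hrmax(age, sex)
            intercept = aeemax - slope * hrmax
            sexcode = 1 if sex == "male" else 0
            x = dict(aeemax=aeemax, slope=slope, percent_body_fat=fat,
                     age=age, sex=sexcode, height=height)
            vo2 = coefs["constant"] + sum(coefs[c] * x[c] for c in COVARIATES)
            vo2 += rng.normal(0.0, config.vo2max_noise_sd) if config.vo2max_noise_sd else 0.0
            resting_hr = float(rng.uniform(*config.resting_hr_range))
            profiles.append(SubjectProfile(
                subject_id=sid, age=age, sex=sex, height=height, weight=weight,
                percent_body_fat=fat, vo2max_measured=vo2,
            ))
            truths.append(GroundTruth(
                subject_id=sid, group=group, true_slope=slope,
                true_intercept=intercept, true_aeemax=aeemax, true_hrmax=hrmax,
                true_vo2max=vo2, resting_hr=resting_hr,
            ))
    return profiles, truths


def _response_aee(hr, slope, intercept, resting_hr):
    """Latent aEE response: linear above the knee, saturating below it."""
    hr = np.asarray(hr, dtype=float)
    lin = slope * hr + intercept
    knee_val = slope * LINEAR_KNEE_BPM + intercept
    frac = np.clip((hr - resting_hr) / (LINEAR_KNEE_BPM - resting_hr), 0.0, 1.0)
    low = REST_AEE + (knee_val - REST_AEE) * frac ** 2
    return np.where(hr >= LINEAR_KNEE_BPM, lin, low)


def simulate_trace(truth: GroundTruth, config: SimConfig, rng=None) -> ActivityTrace:
    """Generate one subject's minute-level trace.

    Each day has a wear window of ``wear_hours_per_day`` hours containing
    ``bout_rate`` ramped activity bouts (heart rate climbs at 5 bpm/min to a
    random fraction of the subject's HRmax, holds briefly, and descends) plus
    a short shower gap; overnight minutes are non-wear. Sensor noise is added
    to the observed heart rate and activity independently.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.days * 1440
    hr_true = np.full(n, truth.resting_hr)
    worn = np.zeros(n, dtype=bool)
    wear_len = int(round(config.wear_hours_per_day * 60))
    for day in range(config.days):
        w0 = day * 1440 + config.wear_start_hour * 60
        w1 = min(w0 + wear_len, (day + 1) * 1440)
        worn[w0:w1] = True
        # shower: a short non-wear block at a random position in the window
        g0 = int(rng.integers(w0, max(w0 + 1, w1 - SHOWER_GAP_MIN)))
        worn[g0:g0 + SHOWER_GAP_MIN] = False
        # bouts placed in equal slots of the wear window so they never overlap
        slot = (w1 - w0) // max(config.bout_rate, 1)
        for b in range(config.bout_rate):
            lo, hi = truth.resting_hr, truth.true_hrmax
            peak = lo + rng.uniform(*config.peak_hr_fraction) * (hi - lo)
            up = np.arange(lo, peak, RAMP_BPM_PER_MIN)[1:]
            # sustained phase: interval-style oscillation around the peak
            # (kept above the HR gate so the response stays in its linear range)
            work = [np.full(int(rng.integers(3, 8)), peak)]
            amp = min(25.0, peak - 125.0)
            if amp >= 2 * RAMP_BPM_PER_MIN:
                for _ in range(int(rng.integers(2, 5))):
                    a = rng.uniform(2 * RAMP_BPM_PER_MIN, amp)
                    leg = np.arange(peak - a, peak, RAMP_BPM_PER_MIN)
                    work.append(leg[::-1])  # ease off
                    work.append(leg[1:])    # push back up
                    work.append(np.full(int(rng.integers(2, 5)), peak))
            down = up[::-1]
            profile = np.concatenate([up, *work, down])
            s0 = w0 + b * slot
            start = int(rng.integers(s0, max(s0 + 1, s0 + slot - len(profile))))
            stop = min(start + len(profile), w1)
            hr_true[start:stop] = profile[: stop - start]
    aee_true = _response_aee(hr_true, truth.true_slope, truth.true_intercept,
                             truth.resting_hr)
    hr_obs = hr_true + (rng.normal(0, config.hr_noise_sd, n) if config.hr_noise_sd else 0.0)
    aee_obs = aee_true + (rng.normal(0, config.aee_noise_sd, n) if config.aee_noise_sd else 0.0)
    hr_obs = np.clip(hr_obs, 30.0, None)
    aee_obs = np.clip(aee_obs, 0.0, None)
    hr_obs[~worn] = np.nan
    aee_obs[~worn] = np.nan
    timestamps = pd.date_range(TRACE_START, periods=n, freq="min")
    return ActivityTrace(subject_id=truth.subject_id, timestamps=timestamps,
                         hr=hr_obs, aee=aee_obs)


def simulate_dataset(config: SimConfig):
    """Cohort plus one trace per subject, all from a single seeded stream."""
    rng = np.random.default_rng(config.seed)
    profiles, truths = simulate_cohort(config, rng)
    traces = [simulate_trace(t, config, rng) for t in truths]
    return profiles, truths, traces
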