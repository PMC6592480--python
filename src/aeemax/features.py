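"""The two fitness features: aEEmax and the HR-activity slope.

For each subject, an ordinary least-squares line ``aee = slope * hr +
intercept`` is fit through the selected high-intensity minutes (smoothed
values). Predicted maximal heart rate comes from sex-specific age formulas;
aEEmax is the activity energy expenditure of that line evaluated at HRmax —
an extrapolation of the subject's observed exertion response to their
predicted maximal effort, obtainable without any maximal exercise test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .exceptions import DegenerateFitError, InsufficientDataError, ParameterError
from .io import ActivityTrace, SubjectProfile
from .preprocess import (
    DEFAULT_HR_GATE,
    DEFAULT_MIN_WEAR_MINUTES,
    DEFAULT_SMOOTH_WINDOW,
    check_sufficiency,
    select_activity_minutes,
)

DEFAULT_MIN_POINTS = 30

#: HRmax = intercept - coefficient * age, by sex
HRMAX_FORMULA = {"female": (200.0, 0.67), "male": (216.0, 0.93)}

#: below roughly one resting MET the extrapolated value is physiologically implausible
AEEMAX_PLAUSIBLE_FLOOR = 1.0


@dataclass
class FeatureSet:
    """Per-subject derived quantities.

    ``aeemax = slope * hrmax + intercept`` holds exactly by construction.
    ``pearson_r_fit`` is the correlation of the per-subject line fit, a
    diagnostic of how linear the subject's HR-activity response was.
    """

    subject_id: str
    hrmax: float
    slope: float
    intercept: float
    aeemax: float
    n_points: int
    pearson_r_fit: float
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "hrmax_bpm": self.hrmax,
            "slope_kcal_kg_h_per_bpm": self.slope,
            "intercept_kcal_kg_h": self.intercept,
            "aeemax_kcal_kg_h": self.aeemax,
            "n_points": self.n_points,
            "pearson_r_fit": self.pearson_r_fit,
            "flags": ";".join(self.flags),
        }


def predicted_hrmax(age: float, sex: str) -> float:
    """Predicted maximal heart rate: 200 - 0.67*age (women), 216 - 0.93*age (men)."""
    if age <= 0:
        raise ParameterError(f"age must be positive, got {age}")
    try:
        base, coef = HRMAX_FORMULA[sex]
    except KeyError:
        raise ParameterError(f"sex must be 'female' or 'male', got {sex!r}") from None
    return base - coef * age


def fit_activity_line(hr_sel, aee_sel, min_points: int = DEFAULT_MIN_POINTS):
    """OLS of activity on heart rate over the selected minutes.

    Returns ``(slope, intercept, pearson_r)`` with slope in kcal/kg/h per
    beat/min. Raises :class:`InsufficientDataError` below ``min_points`` and
    :class:`DegenerateFitError` when heart rate has no variance.
    """
    n = len(hr_sel)
    if n != len(aee_sel):
        raise ParameterError("hr and aee selections differ in length")
    if n < min_points:
        raise InsufficientDataError(
            f"only {n} regression points (minimum {min_points})",
            n_points=n, required=min_points,
        )
    try:
        res = stats.linregress(hr_sel, aee_sel)
    except ValueError as err:
        raise DegenerateFitError(
            f"degenerate heart-rate values in selected minutes: {err}") from None
    if not _finite(res.slope):
        raise DegenerateFitError("zero heart-rate variance in selected minutes")
    return float(res.slope), float(res.intercept), float(res.rvalue)


def aeemax_from_line(slope: float, intercept: float, hrmax: float) -> float:
    """Activity energy expenditure of the regression line at maximal heart rate."""
    return slope * hrmax + intercept


def extract_features(
    trace: ActivityTrace,
    profile: SubjectProfile,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    hr_gate: float = DEFAULT_HR_GATE,
    min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES,
    min_points: int = DEFAULT_MIN_POINTS,
) -> FeatureSet:
    """Full per-subject pipeline: smooth, co-increase, gate, fit, extrapolate."""
    suff = check_sufficiency(trace, min_wear_minutes)
    if not suff.passed:
        raise InsufficientDataError(
            f"{trace.subject_id}: {suff.n_wear_minutes} wear minutes "
            f"(minimum {suff.required_minutes})",
            n_points=suff.n_wear_minutes, required=suff.required_minutes,
            subject_id=trace.subject_id,
        )
    sel, hr_s, aee_s = select_activity_minutes(trace, smooth_window, hr_gate)
    try:
        slope, intercept, r_fit = fit_activity_line(
            hr_s[sel.selected_idx], aee_s[sel.selected_idx], min_points
        )
    except InsufficientDataError as err:
        err.subject_id = trace.subject_id
        raise
    hrmax = predicted_hrmax(profile.age, profile.sex)
    aeemax = aeemax_from_line(slope, intercept, hrmax)
    flags = list(suff.warnings)
    if aeemax < AEEMAX_PLAUSIBLE_FLOOR:
        flags.append(f"implausible aeemax {aeemax:.2f} kcal/kg/h")
    if hrmax <= hr_gate:
        flags.append(f"predicted HRmax {hrmax:.1f} at or below the {hr_gate:.0f} bpm gate")
    return FeatureSet(
        subject_id=trace.subject_id,
        hrmax=hrmax,
        slope=slope,
        intercept=intercept,
        aeemax=aeemax,
        n_points=int(sel.n_after_hr_gate),
        pearson_r_fit=r_fit,
        flags=flags,
    )


def _finite(x) -> bool:
    return x == x and abs(x) != float("inf")
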