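"""Reading and writing the package's file formats.

Minute-level trace CSVs (``timestamp,hr_bpm,aee_kcal_kg_h``), cohort metadata
CSVs (``subject_id,age_years,sex,height_cm,weight_kg,percent_body_fat,
vo2max_ml_kg_min``), per-subject feature CSVs and JSON model/report files.
All files are UTF-8, comma-separated, with a header row; timestamps are
ISO 8601. Missing minutes are never imputed — a row with a blank heart-rate
or activity cell is kept but marked non-wear.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

TRACE_COLUMNS = ("timestamp", "hr_bpm", "aee_kcal_kg_h")
COHORT_COLUMNS = ("subject_id", "age_years", "sex", "height_cm", "weight_kg",
                  "percent_body_fat", "vo2max_ml_kg_min")

_FEMALE_TOKENS = {"female", "f", "0"}
_MALE_TOKENS = {"male", "m", "1"}


@dataclass
class ActivityTrace:
    """Minute-indexed heart rate and activity energy expenditure for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    timestamps : pandas.DatetimeIndex
        Strictly increasing, nominally 1-minute spacing. Gaps are allowed;
        differences are never taken across them.
    hr : ndarray of float
        Heart rate per minute in beats/min; NaN where the device was not worn.
    aee : ndarray of float
        Activity energy expenditure per minute in kcal/kg/h (MET-like);
        NaN where missing.
    """

    subject_id: str
    timestamps: pd.DatetimeIndex
    hr: np.ndarray
    aee: np.ndarray

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.hr = np.asarray(self.hr, dtype=float)
        self.aee = np.asarray(self.aee, dtype=float)
        n = len(self.timestamps)
        if n == 0:
            raise DataError(f"{self.subject_id}: empty trace")
        if len(self.hr) != n or len(self.aee) != n:
            raise DataError(f"{self.subject_id}: hr/aee length does not match timestamps")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise DataError(f"{self.subject_id}: timestamps must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.hr[~np.isnan(self.hr)] <= 0):
                raise DataError(f"{self.subject_id}: nonpositive heart rate")
            if np.any(self.aee[~np.isnan(self.aee)] < 0):
                raise DataError(f"{self.subject_id}: negative activity energy expenditure")

    @property
    def wear_mask(self) -> np.ndarray:
        """True where both heart rate and activity are present."""
        return ~np.isnan(self.hr) & ~np.isnan(self.aee)

    @property
    def n_wear_minutes(self) -> int:
        return int(self.wear_mask.sum())

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "hr_bpm": self.hr, "aee_kcal_kg_h": self.aee}
        )


@dataclass
class SubjectProfile:
    """Anthropometrics and demographics for one subject.

    ``age`` in years, ``height`` in cm, ``weight`` in kg, ``percent_body_fat``
    in %, ``vo2max_measured`` in mL/kg/min (optional: present only for
    subjects with a reference graded-exercise-test measurement).
    """

    subject_id: str
    age: float
    sex: str  # "female" or "male"
    height: float
    weight: float | None = None
    percent_body_fat: float | None = None
    vo2max_measured: float | None = None

    def __post_init__(self):
        self.sex = parse_sex(self.sex)
        if self.age is None or self.age <= 0:
            raise DataError(f"{self.subject_id}: age must be positive")
        if self.height is None or self.height <= 0:
            raise DataError(f"{self.subject_id}: height must be positive")
        if self.percent_body_fat is not None and not (0 < self.percent_body_fat < 100):
            raise DataError(f"{self.subject_id}: percent body fat outside (0, 100)")

    @property
    def sex_code(self) -> int:
        """Model coding: female=0, male=1."""
        return 1 if self.sex == "male" else 0


def parse_sex(token) -> str:
    """Normalise a sex token to 'female'/'male' (case-insensitive; accepts f/m/0/1)."""
    s = str(token).strip().lower()
    if s in _FEMALE_TOKENS:
        return "female"
    if s in _MALE_TOKENS:
        return "male"
    raise FormatError(f"unparseable sex token: {token!r}")


def read_trace(path, subject_id: str | None = None) -> ActivityTrace:
    """Read a minute-level trace CSV into an :class:`ActivityTrace`.

    Rows with a blank heart-rate or activity cell are retained as non-wear
    minutes. Out-of-order or duplicate timestamps are an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty trace file") from None
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate columns")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")
    ts = pd.to_datetime(df["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise DataError(f"{path}: timestamps not strictly increasing")
    sid = subject_id if subject_id is not None else path.stem
    return ActivityTrace(
        subject_id=sid,
        timestamps=pd.DatetimeIndex(ts),
        hr=df["hr_bpm"].to_numpy(dtype=float),
        aee=df["aee_kcal_kg_h"].to_numpy(dtype=float),
    )


def write_trace(trace: ActivityTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_cohort(path) -> list[SubjectProfile]:
    """Read a cohort metadata CSV into a list of :class:`SubjectProfile`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty cohort file") from None
    missing = {"subject_id", "age_years", "sex", "height_cm"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"{path}: duplicate subject_id {dups}")

    def _opt(row, col):
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    profiles = []
    for _, row in df.iterrows():
        profiles.append(SubjectProfile(
            subject_id=str(row["subject_id"]),
            age=float(row["age_years"]),
            sex=row["sex"],
            height=float(row["height_cm"]),
            weight=_opt(row, "weight_kg"),
            percent_body_fat=_opt(row, "percent_body_fat"),
            vo2max_measured=_opt(row, "vo2max_ml_kg_min"),
        ))
    return profiles


def write_cohort(profiles, path) -> None:
    rows = []
    for p in profiles:
        rows.append({
            "subject_id": p.subject_id,
            "age_years": p.age,
            "sex": p.sex,
            "height_cm": p.height,
            "weight_kg": p.weight,
            "percent_body_fat": p.percent_body_fat,
            "vo2max_ml_kg_min": p.vo2max_measured,
        })
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def write_features(features, path) -> None:
    """Write per-subject feature rows to CSV (one row per subject)."""
    rows = [f.to_dict() for f in features]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    """Serialise a dataclass or dict to JSON with stable key order."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serialisable: {type(o)}")
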