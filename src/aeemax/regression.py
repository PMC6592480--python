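"""The nonexercise VO2max multiple linear regression.

The model estimates maximal oxygen uptake (mL/kg/min) from six covariates:
the two tracker-derived features (aEEmax in kcal/kg/h and the HR-activity
slope in kcal/kg/h/bpm) and four anthropometric/demographic covariates
(percent body fat, age in years, sex coded female=0/male=1, height in cm).

The API follows the statsmodels idiom: :class:`VO2maxModel` is built from a
cohort DataFrame and ``fit()`` returns a :class:`VO2maxResults` carrying the
coefficients, their standard errors, standardized coefficients, in-sample
fit metrics (R, R², SEE) and the PRESS leave-one-out cross-validated
metrics (R_P, SEE_P). ``published_model()`` returns the fixed published
coefficient vector for out-of-the-box prediction.

PRESS (predicted residual error sum of squares) is the sum of squared
leave-one-out prediction errors. It is computed in closed form from the hat
matrix: for OLS, the leave-one-out residual for case i equals
``e_i / (1 - h_ii)`` where ``e_i`` is the ordinary residual and ``h_ii``
the leverage, so no refitting is needed. R_P = sqrt(1 - PRESS/SS) with SS
the total sum of squares of the response; SEE_P = sqrt(PRESS/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DataError, DegenerateFitError
from .features import FeatureSet
from .io import read_json, write_json

COVARIATES = ("aeemax", "slope", "percent_body_fat", "age", "sex", "height")
PARAM_NAMES = ("constant",) + COVARIATES

#: Published coefficient vector (constant, aEEmax, slope, percent body fat,
#: age, sex, height) and its reported fit metrics on the 191-subject
#: development cohort.
PUBLISHED_COEFFICIENTS = {
    "constant": 63.262,
    "aeemax": 0.027,
    "slope": -1.776,
    "percent_body_fat": -0.242,
    "age": -0.150,
    "sex": 3.264,
    "height": -0.09,
}
PUBLISHED_BETAS = {
    "aeemax": 0.082,
    "slope": -0.045,
    "percent_body_fat": -0.296,
    "age": -0.321,
    "sex": 0.548,
    "height": -0.166,
}
PUBLISHED_METRICS = {"n": 191, "r": 0.807, "see": 3.518, "r_p": 0.787, "see_p": 3.667}

N_PARAMS = len(PARAM_NAMES)


def cohort_frame(features, profiles) -> pd.DataFrame:
    """Merge per-subject features and profiles into one modelling DataFrame.

    Columns: ``subject_id, vo2max, aeemax, slope, percent_body_fat, age,
    sex (0/1), height``. Subjects missing from either side are dropped.
    """
    prof = {p.subject_id: p for p in profiles}
    rows = []
    for f in features:
        p = prof.get(f.subject_id)
        if p is None:
            continue
        rows.append({
            "subject_id": f.subject_id,
            "vo2max": p.vo2max_measured,
            "aeemax": f.aeemax,
            "slope": f.slope,
            "percent_body_fat": p.percent_body_fat,
            "age": p.age,
            "sex": p.sex_code,
            "height": p.height,
        })
    return pd.DataFrame(rows)


def _design_matrix(data: pd.DataFrame) -> np.ndarray:
    missing = [c for c in COVARIATES if c not in data.columns]
    if missing:
        raise DataError(f"missing covariate columns: {missing}")
    X = data.loc[:, list(COVARIATES)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in COVARIATES if data[c].isna().any()]
        raise DataError(f"missing covariate values in columns: {bad}")
    return np.column_stack([np.ones(len(X)), X])


class VO2maxModel:
    """Multiple linear regression of measured VO2max on the six covariates.

    Parameters
    ----------
    data : DataFrame
        One row per subject with columns ``vo2max`` (the response, mL/kg/min)
        and the covariates ``aeemax, slope, percent_body_fat, age, sex,
        height``. Sex may be numeric (0/1) or the strings female/male.
    """

    def __init__(self, data: pd.DataFrame, response: str = "vo2max"):
        data = data.copy()
        if response not in data.columns:
            raise DataError(f"response column {response!r} not found")
        if "sex" in data.columns and data["sex"].dtype == object:
            data["sex"] = (
                data["sex"].astype(str).str.strip().str.lower()
                .map({"female": 0, "f": 0, "0": 0, "male": 1, "m": 1, "1": 1})
            )
        self.data = data
        self.endog = data[response].to_numpy(dtype=float)
        if np.isnan(self.endog).any():
            raise DataError("missing measured VO2max in response column")
        self.exog = _design_matrix(data)
        n, p = self.exog.shape
        if n <= p + 1:
            raise DataError(f"need more than {p + 1} subjects, got {n}")
        if np.linalg.matrix_rank(self.exog) < p:
            raise DegenerateFitError("rank-deficient design (collinear covariates)")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str = "vo2max") -> "VO2maxModel":
        return cls(data, response=response)

    @classmethod
    def from_features(cls, features, profiles) -> "VO2maxModel":
        """Build the model from extracted features plus cohort profiles."""
        return cls(cohort_frame(features, profiles))

    def fit(self, see_p_denominator: str = "n") -> "VO2maxResults":
        """OLS fit with PRESS leave-one-out cross-validation.

        ``see_p_denominator`` selects the SEE_P convention: ``"n"`` (default)
        for sqrt(PRESS/n) or ``"n-p"`` for sqrt(PRESS/(n-7)).
        """
        ols = sm.OLS(self.endog, self.exog).fit()
        n = len(self.endog)
        resid = np.asarray(ols.resid)
        sse = float(resid @ resid)
        see = float(np.sqrt(sse / (n - N_PARAMS)))
        fitted = np.asarray(ols.fittedvalues)
        r = float(stats.pearsonr(self.endog, fitted)[0])

        press, r_p, see_p = press_cv(
            self.exog, self.endog, see_p_denominator=see_p_denominator
        )

        y = self.endog
        sd_y = float(np.std(y, ddof=1))
        betas = {
            name: float(ols.params[i + 1]) * float(np.std(self.exog[:, i + 1], ddof=1)) / sd_y
            for i, name in enumerate(COVARIATES)
        }
        return VO2maxResults(
            params=pd.Series(np.asarray(ols.params), index=list(PARAM_NAMES)),
            bse=pd.Series(np.asarray(ols.bse), index=list(PARAM_NAMES)),
            betas=pd.Series(betas, index=list(COVARIATES)),
            n=n,
            r=r,
            r2=r * r,
            r2_adj=float(ols.rsquared_adj),
            see=see,
            press=press,
            r_p=r_p,
            see_p=see_p,
            model=self,
            resid=resid,
            fittedvalues=fitted,
        )


@dataclass
class VO2maxResults:
    """Fitted (or published) model coefficients with fit and PRESS metrics."""

    params: pd.Series
    bse: pd.Series | None
    betas: pd.Series
    n: int
    r: float
    r2: float
    r2_adj: float | None
    see: float
    press: float | None
    r_p: float
    see_p: float
    model: VO2maxModel | None = None
    resid: np.ndarray | None = None
    fittedvalues: np.ndarray | None = None

    def predict(self, covariates) -> np.ndarray | float:
        """Estimated VO2max (mL/kg/min) for new subjects.

        ``covariates`` may be a DataFrame with the six covariate columns, a
        mapping, or a ``(FeatureSet, SubjectProfile)`` pair.
        """
        scalar = False
        if isinstance(covariates, tuple) and len(covariates) == 2 \
                and isinstance(covariates[0], FeatureSet):
            feat, prof = covariates
            covariates = {
                "aeemax": feat.aeemax, "slope": feat.slope,
                "percent_body_fat": prof.percent_body_fat,
                "age": prof.age, "sex": prof.sex_code, "height": prof.height,
            }
        if isinstance(covariates, dict):
            covariates = pd.DataFrame([covariates])
            scalar = True
        df = covariates.copy()
        if "sex" in df.columns and df["sex"].dtype == object:
            df["sex"] = (
                df["sex"].astype(str).str.strip().str.lower()
                .map({"female": 0, "f": 0, "0": 0, "male": 1, "m": 1, "1": 1})
            )
        X = _design_matrix(df)
        yhat = X @ self.params.to_numpy()
        return float(yhat[0]) if scalar else yhat

    def subgroup_validation(self, data: pd.DataFrame | None = None,
                            age_cut: float | None = None,
                            vo2max_cut: float | None = None) -> "ValidationReport":
        """Constant-error validation over sex / age / VO2max-level subgroups."""
        if data is None:
            if self.model is None:
                raise DataError("no attached data; pass a cohort DataFrame")
            data = self.model.data
        return subgroup_validation(self, data, age_cut=age_cut, vo2max_cut=vo2max_cut)

    def summary(self) -> str:
        """Plain-text coefficient table with the fit and cross-validated metrics."""
        lines = []
        lines.append("Nonexercise VO2max estimation model (mL/kg/min)")
        lines.append("=" * 56)
        lines.append(f"{'variable':<20}{'coef':>12}{'beta':>10}{'SE':>12}")
        lines.append("-" * 56)
        for name in PARAM_NAMES:
            coef = self.params[name]
            beta = f"{self.betas[name]:.3f}" if name in self.betas.index else "-"
            se = f"{self.bse[name]:.3f}" if self.bse is not None else "-"
            lines.append(f"{name:<20}{coef:>12.3f}{beta:>10}{se:>12}")
        lines.append("-" * 56)
        lines.append(f"n subjects          {self.n:>12d}")
        lines.append(f"R                   {self.r:>12.3f}")
        lines.append(f"R^2                 {self.r2:>12.3f}")
        if self.r2_adj is not None:
            lines.append(f"adjusted R^2        {self.r2_adj:>12.3f}")
        lines.append(f"SEE (mL/kg/min)     {self.see:>12.3f}")
        lines.append(f"R_P                 {self.r_p:>12.3f}")
        lines.append(f"SEE_P (mL/kg/min)   {self.see_p:>12.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "betas": {k: float(v) for k, v in self.betas.items()},
            "standard_errors": (
                {k: float(v) for k, v in self.bse.items()} if self.bse is not None else None
            ),
            "n": int(self.n),
            "r": self.r, "r2": self.r2, "r2_adj": self.r2_adj,
            "see": self.see, "press": self.press,
            "r_p": self.r_p, "see_p": self.see_p,
        }

    def save(self, path) -> None:
        write_json(self.to_dict(), path)

    @classmethod
    def from_dict(cls, d: dict) -> "VO2maxResults":
        bse = d.get("standard_errors")
        return cls(
            params=pd.Series({k: d["coefficients"][k] for k in PARAM_NAMES}),
            bse=pd.Series({k: bse[k] for k in PARAM_NAMES}) if bse else None,
            betas=pd.Series({k: d["betas"][k] for k in d["betas"]}),
            n=d["n"], r=d["r"], r2=d["r2"], r2_adj=d.get("r2_adj"),
            see=d["see"], press=d.get("press"), r_p=d["r_p"], see_p=d["see_p"],
        )

    @classmethod
    def load(cls, path) -> "VO2maxResults":
        return cls.from_dict(read_json(path))


def published_model() -> VO2maxResults:
    """The published coefficient vector with its reported metrics.

    Metrics are the values reported for the development cohort (n=191),
    not recomputed — that cohort is not publicly available.
    """
    m = PUBLISHED_METRICS
    return VO2maxResults(
        params=pd.Series(PUBLISHED_COEFFICIENTS, index=list(PARAM_NAMES)),
        bse=None,
        betas=pd.Series(PUBLISHED_BETAS, index=list(COVARIATES)),
        n=m["n"], r=m["r"], r2=m["r"] ** 2, r2_adj=None,
        see=m["see"], press=None, r_p=m["r_p"], see_p=m["see_p"],
    )


def press_cv(design, response, see_p_denominator: str = "n"):
    """Leave-one-out PRESS statistics via the hat-matrix closed form.

    Returns ``(press, r_p, see_p)``. ``design`` must already include the
    intercept column. Equivalent to refitting the model n times, each time
    predicting the held-out case.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateFitError("rank-deficient design")
    ols = sm.OLS(y, X).fit()
    h = ols.get_influence().hat_matrix_diag
    if np.any(h >= 1 - 1e-12):
        bad = int(np.argmax(h))
        raise DegenerateFitError(
            f"leverage 1 at case {bad}: leave-one-out prediction undefined"
        )
    loo_resid = np.asarray(ols.resid) / (1.0 - h)
    press = float(loo_resid @ loo_resid)
    ss = float(np.sum((y - y.mean()) ** 2))
    r_p = float(np.sqrt(max(0.0, 1.0 - press / ss)))
    if see_p_denominator == "n":
        see_p = float(np.sqrt(press / n))
    elif see_p_denominator in ("n-p", "n-7"):
        see_p = float(np.sqrt(press / (n - p)))
    else:
        raise DataError(f"unknown see_p_denominator {see_p_denominator!r}")
    return press, r_p, see_p


@dataclass
class SubgroupRow:
    group: str
    n: int
    ce: float
    sd: float


@dataclass
class ValidationReport:
    """Constant error (mean of measured - estimated) and SD per subgroup."""

    rows: list
    age_cut: float
    vo2max_cut: float

    def to_dict(self) -> dict:
        return {
            "splits": {"age_cut_years": self.age_cut,
                       "vo2max_cut_ml_kg_min": self.vo2max_cut},
            "subgroups": [
                {"group": r.group, "n": r.n, "ce": r.ce, "sd": r.sd} for r in self.rows
            ],
        }

    def save(self, path) -> None:
        write_json(self.to_dict(), path)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"group": r.group, "n": r.n, "ce": r.ce, "sd": r.sd} for r in self.rows
        ])


def subgroup_validation(results: VO2maxResults, data: pd.DataFrame,
                        age_cut: float | None = None,
                        vo2max_cut: float | None = None,
                        response: str = "vo2max") -> ValidationReport:
    """Constant error by sex, age group and VO2max level.

    CE = mean(measured - estimated); a near-zero CE means the model neither
    over- nor under-estimates that subgroup systematically. Default cuts are
    the cohort medians (older/fitter = strictly above the cut); pass
    ``age_cut=40, vo2max_cut=36`` to use the published splits.
    """
    if response not in data.columns or data[response].isna().any():
        raise DataError("measured VO2max required for every subject")
    measured = data[response].to_numpy(dtype=float)
    estimated = results.predict(data)
    err = measured - estimated
    if age_cut is None:
        age_cut = float(np.median(data["age"]))
    if vo2max_cut is None:
        vo2max_cut = float(np.median(measured))

    sex = data["sex"]
    if sex.dtype == object:
        sex = sex.astype(str).str.strip().str.lower().map(
            {"female": 0, "f": 0, "0": 0, "male": 1, "m": 1, "1": 1})
    sex = sex.to_numpy(dtype=float)
    age = data["age"].to_numpy(dtype=float)

    groups = [
        ("female", sex == 0),
        ("male", sex == 1),
        ("old", age > age_cut),
        ("young", age <= age_cut),
        ("high_vo2max", measured > vo2max_cut),
        ("low_vo2max", measured <= vo2max_cut),
    ]
    rows = []
    for label, mask in groups:
        k = int(mask.sum())
        if k == 0:
            rows.append(SubgroupRow(group=label, n=0, ce=float("nan"), sd=float("nan")))
            continue
        e = err[mask]
        sd = float(np.std(e, ddof=1)) if k > 1 else float("nan")
        rows.append(SubgroupRow(group=label, n=k, ce=float(e.mean()), sd=sd))
    return ValidationReport(rows=rows, age_cut=age_cut, vo2max_cut=vo2max_cut)


CORRELATION_VARIABLES = ("vo2max", "age", "height", "sex", "percent_body_fat",
                         "aeemax", "slope")


def correlation_table(data: pd.DataFrame, variables=CORRELATION_VARIABLES):
    """Pairwise Pearson correlations (and two-sided p-values) among the
    response and the model covariates. Zero-variance columns yield NaN."""
    if len(data) < 3:
        raise DataError("need at least 3 subjects for correlations")
    cols = [v for v in variables if v in data.columns]
    df = data.loc[:, cols].copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = df["sex"].astype(str).str.strip().str.lower().map(
            {"female": 0, "f": 0, "0": 0, "male": 1, "m": 1, "1": 1})
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x = df[a].to_numpy(dtype=float)
            y = df[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p
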