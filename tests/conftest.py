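import numpy as np
import pandas as pd
import pytest

from aeemax.io import ActivityTrace, SubjectProfile
from aeemax.regression import COVARIATES


def make_trace(hr, aee, subject_id="T1", start="2024-01-06 07:00"):
    """Trace from plain lists; None becomes a non-wear minute."""
    hr = np.array([np.nan if v is None else float(v) for v in hr])
    aee = np.array([np.nan if v is None else float(v) for v in aee])
    ts = pd.date_range(start, periods=len(hr), freq="min")
    return ActivityTrace(subject_id=subject_id, timestamps=ts, hr=hr, aee=aee)


@pytest.fixture
def rng():
    return np.random.default_rng(20240106)


@pytest.fixture
def profile_male():
    return SubjectProfile(subject_id="T1", age=27, sex="male", height=174.3,
                          weight=73.9, percent_body_fat=20.4)


def random_cohort_frame(rng, n=40, noise_sd=0.0, coefs=None):
    """Covariate frame with a known linear response, for model-fitting tests."""
    if coefs is None:
        coefs = {"constant": 60.0, "aeemax": 0.03, "slope": -1.5,
                 "percent_body_fat": -0.25, "age": -0.15, "sex": 3.0, "height": -0.08}
    df = pd.DataFrame({
        "aeemax": rng.normal(120, 15, n),
        "slope": rng.normal(1.0, 0.15, n),
        "percent_body_fat": rng.normal(27, 6, n),
        "age": rng.integers(20, 66, n).astype(float),
        "sex": rng.integers(0, 2, n).astype(float),
        "height": rng.normal(165, 8, n),
    })
    y = coefs["constant"] + sum(coefs[c] * df[c] for c in COVARIATES)
    df["vo2max"] = y + (rng.normal(0, noise_sd, n) if noise_sd else 0.0)
    return df, coefs
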