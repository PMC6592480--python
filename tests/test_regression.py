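import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeemax import (DataError, DegenerateFitError, VO2maxModel, correlation_table,
                    press_cv, published_model, subgroup_validation)
from aeemax.regression import COVARIATES, PARAM_NAMES

from conftest import random_cohort_frame


def brute_force_press(X, y):
    """Independent oracle: refit with each case held out, predict it."""
    n = len(y)
    errs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        errs[i] = y[i] - X[i] @ beta
    return float(errs @ errs)


def _design(rng, n, p=6):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    y = X @ rng.normal(size=p + 1) + rng.normal(0, 2, n)
    return X, y


class TestFit:
    def test_noiseless_response_identified_exactly(self, rng):
        df, coefs = random_cohort_frame(rng, n=60, noise_sd=0.0)
        res = VO2maxModel.from_dataframe(df).fit()
        for name in PARAM_NAMES:
            assert res.params[name] == pytest.approx(coefs[name], abs=1e-8)
        assert res.see == pytest.approx(0.0, abs=1e-8)
        assert res.r == pytest.approx(1.0, abs=1e-10)
        assert res.r2 == pytest.approx(res.r ** 2, abs=1e-12)

    def test_noisy_fit_recovers_within_3se(self, rng):
        df, coefs = random_cohort_frame(rng, n=191, noise_sd=3.5)
        res = VO2maxModel.from_dataframe(df).fit()
        for name in PARAM_NAMES:
            assert abs(res.params[name] - coefs[name]) <= 3 * res.bse[name]

    def test_collinear_design_rejected(self, rng):
        df, _ = random_cohort_frame(rng, n=40, noise_sd=1.0)
        df["height"] = df["age"]  # duplicate covariate (up to renaming)
        with pytest.raises(DegenerateFitError):
            VO2maxModel.from_dataframe(df)

    def test_missing_covariate_rejected(self, rng):
        df, _ = random_cohort_frame(rng, n=40, noise_sd=1.0)
        df.loc[3, "percent_body_fat"] = np.nan
        with pytest.raises(DataError):
            VO2maxModel.from_dataframe(df)

    def test_betas_are_standardised_coefficients(self, rng):
        df, _ = random_cohort_frame(rng, n=80, noise_sd=2.0)
        res = VO2maxModel.from_dataframe(df).fit()
        for c in COVARIATES:
            expected = res.params[c] * df[c].std(ddof=1) / df["vo2max"].std(ddof=1)
            assert res.betas[c] == pytest.approx(expected, rel=1e-10)

    def test_summary_reports_all_metrics(self, rng):
        df, _ = random_cohort_frame(rng, n=40, noise_sd=2.0)
        text = VO2maxModel.from_dataframe(df).fit().summary()
        for token in ("R_P", "SEE_P", "aeemax", "slope", "sex"):
            assert token in text


class TestPublishedModel:
    def test_coefficient_vector(self):
        res = published_model()
        assert res.params["constant"] == 63.262
        assert res.params["sex"] == 3.264
        assert res.params["height"] == -0.09
        assert res.see == 3.518 and res.r_p == 0.787 and res.see_p == 3.667

    def test_worked_example_prediction(self):
        cov = dict(aeemax=141.0, slope=1.10, percent_body_fat=20.4,
                   age=27, sex=1, height=174.3)
        assert published_model().predict(cov) == pytest.approx(43.706, abs=1e-3)

    def test_intercept_only_for_zero_covariates(self):
        cov = dict.fromkeys(COVARIATES, 0.0)
        assert published_model().predict(cov) == pytest.approx(63.262, abs=1e-12)

    def test_sex_contrast_is_exactly_the_sex_coefficient(self):
        cov = dict(aeemax=120.0, slope=1.0, percent_body_fat=25.0,
                   age=40, sex=0, height=165.0)
        pm = published_model()
        assert pm.predict(dict(cov, sex=1)) - pm.predict(cov) == pytest.approx(
            3.264, abs=1e-12)

    def test_predict_is_affine_per_covariate(self):
        pm = published_model()
        base = dict(aeemax=120.0, slope=1.0, percent_body_fat=25.0,
                    age=40, sex=0, height=165.0)
        for c in COVARIATES:
            bumped = dict(base, **{c: base[c] + 2.0})
            assert pm.predict(bumped) - pm.predict(base) == pytest.approx(
                2.0 * pm.params[c], abs=1e-9)

    def test_accepts_sex_strings(self):
        pm = published_model()
        a = pm.predict(dict(aeemax=120, slope=1.0, percent_body_fat=25,
                            age=40, sex="male", height=165))
        b = pm.predict(dict(aeemax=120, slope=1.0, percent_body_fat=25,
                            age=40, sex=1, height=165))
        assert a == pytest.approx(b, abs=1e-12)


class TestPress:
    def test_noiseless_press_is_zero(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 6))])
        y = X @ rng.normal(size=7)
        press, r_p, see_p = press_cv(X, y)
        assert press == pytest.approx(0.0, abs=1e-16)
        assert r_p == pytest.approx(1.0)

    def test_closed_form_equals_brute_force_refit(self, rng):
        X, y = _design(rng, 12)
        press, _, _ = press_cv(X, y)
        assert press == pytest.approx(brute_force_press(X, y), rel=1e-10)

    @given(seed=st.integers(0, 100_000), n=st.integers(12, 50))
    @settings(max_examples=40, deadline=None)
    def test_closed_form_equals_brute_force_property(self, seed, n):
        X, y = _design(np.random.default_rng(seed), n)
        press, _, _ = press_cv(X, y)
        assert press == pytest.approx(brute_force_press(X, y), rel=1e-8)

    def test_cv_dominance(self, rng):
        df, _ = random_cohort_frame(rng, n=50, noise_sd=4.0)
        res = VO2maxModel.from_dataframe(df).fit()
        assert res.see_p >= res.see
        assert res.r_p <= res.r

    def test_unit_leverage_reported(self, rng):
        # case 0 is the only one with a nonzero last column -> leverage 1
        X = np.column_stack([np.ones(10), rng.normal(size=(10, 5)),
                             np.eye(10)[:, 0]])
        y = rng.normal(size=10)
        with pytest.raises(DegenerateFitError, match="case 0"):
            press_cv(X, y)

    def test_see_p_denominator_options(self, rng):
        X, y = _design(rng, 30)
        press, _, see_p_n = press_cv(X, y, see_p_denominator="n")
        _, _, see_p_np = press_cv(X, y, see_p_denominator="n-p")
        assert see_p_n == pytest.approx(np.sqrt(press / 30))
        assert see_p_np == pytest.approx(np.sqrt(press / 23))


class TestSubgroupValidation:
    def test_whole_sample_and_sex_ce_vanish(self, rng):
        df, _ = random_cohort_frame(rng, n=80, noise_sd=4.0)
        res = VO2maxModel.from_dataframe(df).fit()
        rep = res.subgroup_validation()
        frame = rep.as_frame().set_index("group")
        # residuals orthogonal to intercept and to the included sex indicator
        assert abs(frame.loc["female", "ce"]) < 1e-8
        assert abs(frame.loc["male", "ce"]) < 1e-8
        whole = (frame.loc["female", "ce"] * frame.loc["female", "n"]
                 + frame.loc["male", "ce"] * frame.loc["male", "n"]) / 80
        assert abs(whole) < 1e-8
        assert frame["n"].loc[["female", "male"]].sum() == 80
        assert frame["n"].loc[["old", "young"]].sum() == 80

    def test_high_low_vo2max_ce_signs(self, rng):
        df, _ = random_cohort_frame(rng, n=120, noise_sd=4.0)
        res = VO2maxModel.from_dataframe(df).fit()
        frame = res.subgroup_validation().as_frame().set_index("group")
        # regression to the mean: fitted values shrink toward the centre
        assert frame.loc["high_vo2max", "ce"] > 0
        assert frame.loc["low_vo2max", "ce"] < 0

    def test_published_splits_override(self, rng):
        df, _ = random_cohort_frame(rng, n=60, noise_sd=4.0)
        res = VO2maxModel.from_dataframe(df).fit()
        rep = res.subgroup_validation(age_cut=40, vo2max_cut=36)
        assert rep.age_cut == 40 and rep.vo2max_cut == 36
        frame = rep.as_frame().set_index("group")
        assert frame.loc["old", "n"] == (df["age"] > 40).sum()

    def test_empty_subgroup_flagged(self, rng):
        df, _ = random_cohort_frame(rng, n=40, noise_sd=2.0)
        df["sex"] = 1.0  # all male: female subgroup empty
        res = subgroup_validation(published_model(), df)
        frame = res.as_frame().set_index("group")
        assert frame.loc["female", "n"] == 0
        assert np.isnan(frame.loc["female", "ce"])


class TestCorrelationTable:
    def test_diagonal_and_antilinear(self):
        df = pd.DataFrame({"vo2max": [40.0, 35, 30, 25, 20],
                           "age": [20.0, 30, 40, 50, 60]})
        r, p = correlation_table(df, variables=("vo2max", "age"))
        assert r.loc["vo2max", "vo2max"] == 1.0
        assert r.loc["vo2max", "age"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        df, _ = random_cohort_frame(rng, n=5, noise_sd=3.0)
        r, _ = correlation_table(df)
        for a, b in [("vo2max", "aeemax"), ("age", "height")]:
            x, y = df[a].to_numpy(), df[b].to_numpy()
            expected = (np.mean(x * y) - x.mean() * y.mean()) / (np.std(x) * np.std(y))
            assert r.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_flagged(self, rng):
        df, _ = random_cohort_frame(rng, n=20, noise_sd=1.0)
        df["sex"] = 1.0
        r, p = correlation_table(df)
        assert np.isnan(r.loc["sex", "vo2max"])

    def test_needs_three_subjects(self, rng):
        df, _ = random_cohort_frame(rng, n=2, noise_sd=0.0)
        with pytest.raises(DataError):
            correlation_table(df)
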