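"""Poisson hazard fitting: closed forms, independent optimizer cross-checks,
standardization, and gradient-of-risk inference."""

import math

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from fracgr import config, persontime, poisson, synthetic
from fracgr.poisson import (ModelSpec, SeparationError, fit_competing,
                            fit_poisson, fit_poisson_hazard, gradient_of_risk,
                            standardize_exposure)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_simple():
    z, sds = standardize_exposure([1.0, 2.0, 3.0], ["a", "a", "a"])
    np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
    assert sds == {"a": 1.0}


def test_standardize_within_cohort():
    z, sds = standardize_exposure([1, 2, 3, 10, 20, 30],
                                  ["a", "a", "a", "b", "b", "b"])
    np.testing.assert_allclose(z[:3], z[3:])
    assert sds["b"] == pytest.approx(10.0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(a=st.floats(min_value=0.01, max_value=100.0),
       b=st.floats(min_value=-50.0, max_value=50.0))
def test_standardize_affine_invariance(a, b):
    x = np.array([3.0, 7.0, 1.0, 12.0, 5.0])
    g = ["c"] * len(x)
    z0, _ = standardize_exposure(x, g)
    z1, _ = standardize_exposure(a * x + b, g)
    np.testing.assert_allclose(z0, z1, atol=1e-9)


def test_standardize_zero_sd_names_cohort():
    with pytest.raises(ValueError, match="bad_cohort"):
        standardize_exposure([1.0, 1.0, 1.0], ["bad_cohort"] * 3)


# ---------------------------------------------------------------------------
# likelihood maximization
# ---------------------------------------------------------------------------

def _random_instance(rng, n, p):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    dt = rng.uniform(0.3, 1.0, n) / 12.0
    beta = np.concatenate([[math.log(2.0)], rng.normal(0, 0.5, p)])
    lam = np.exp(X @ beta)
    y = (rng.random(n) < 1 - np.exp(-lam * dt)).astype(float)
    return X, y, dt


def test_intercept_only_closed_form():
    rng = np.random.default_rng(0)
    X, y, dt = _random_instance(rng, 500, 0)
    fit = fit_poisson(X, y, dt)
    assert fit.beta[0] == pytest.approx(math.log(y.sum() / dt.sum()), abs=1e-8)


def test_score_vanishes_and_information_psd():
    rng = np.random.default_rng(1)
    X, y, dt = _random_instance(rng, 2000, 3)
    fit = fit_poisson(X, y, dt)
    assert fit.converged
    mu = np.exp(X @ fit.beta + np.log(dt))
    score = X.T @ (y - mu)
    assert np.abs(score).max() < 1e-6 * fit.n_events
    # observed information is PSD at the optimum and at arbitrary points
    for beta in (fit.beta, rng.normal(0, 1, X.shape[1]),
                 rng.normal(0, 1, X.shape[1])):
        m = np.exp(np.clip(X @ beta + np.log(dt), None, 30))
        H = X.T @ (m[:, None] * X)
        assert np.linalg.eigvalsh(H).min() >= -1e-8


def test_matches_statsmodels_glm():
    """Independent cross-check: statsmodels GLM Poisson with exposure."""
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    X, y, dt = _random_instance(rng, 3000, 3)
    fit = fit_poisson(X, y, dt)
    ref = sm.GLM(y, X, family=sm.families.Poisson(), exposure=dt).fit()
    np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(fit.se(), ref.bse, rtol=1e-4)


def test_no_events_raises():
    X = np.ones((10, 1))
    with pytest.raises(ValueError, match="event"):
        fit_poisson(X, np.zeros(10), np.full(10, 1 / 12))


def test_separation_detected():
    rng = np.random.default_rng(3)
    n = 400
    y = (rng.random(n) < 0.1).astype(float)
    X = np.column_stack([np.ones(n), y])  # perfectly predictive covariate
    with pytest.raises(SeparationError):
        fit_poisson(X, y, np.full(n, 1 / 12))


# ---------------------------------------------------------------------------
# hazard-model wrapper on person-months
# ---------------------------------------------------------------------------

def _fitted_cohort(n=1500, seed=21, outcome="any", **spec_kw):
    cfg = replace(config.default_configs(seed=seed)["HK"], n=n,
                  frax_missing_prob=0.0)
    df = synthetic.generate_cohort(cfg)
    pm = persontime.expand_cohort(df, outcome)
    spec = ModelSpec(outcome=outcome, exposure="muscle_density", **spec_kw)
    return df, pm, fit_poisson_hazard(pm, spec)


def test_hazard_fit_converges_with_expected_columns():
    _, _, fit = _fitted_cohort()
    assert fit.converged
    assert fit.names == ["intercept", "time", "age", "muscle_density"]
    assert fit.exposure_sd["HK"] == pytest.approx(3.6, abs=0.3)
    assert fit.n_events <= fit.n_intervals


def test_permuted_exposure_is_null():
    df, pm, _ = _fitted_cohort(seed=22)
    rng = np.random.default_rng(0)
    perm = df.set_index("subject_id")["density"].sample(
        frac=1.0, random_state=7)
    perm.index = df["subject_id"]
    pm = pm.drop(columns=["density"]).merge(
        perm.rename("density"), left_on="subject_id", right_index=True)
    fit = fit_poisson_hazard(pm, ModelSpec(outcome="any",
                                           exposure="muscle_density"))
    j = fit.exposure_index
    assert abs(fit.beta[j]) < 3 * math.sqrt(fit.cov[j, j])


def test_gr_invariant_to_exposure_units():
    """cm² vs mm² (×100) gives the identical per-SD hazard ratio."""
    df, pm, fit_cm = _fitted_cohort(seed=23)
    pm2 = pm.copy()
    pm2["density"] = pm2["density"] * 100.0
    pm2 = pm2.drop(columns=[c for c in pm2.columns if c.endswith("_std")],
                   errors="ignore")
    fit_mm = fit_poisson_hazard(pm2, ModelSpec(outcome="any",
                                               exposure="muscle_density"))
    assert gradient_of_risk(fit_cm).hr == pytest.approx(
        gradient_of_risk(fit_mm).hr, rel=1e-8)


def test_adjusted_fit_and_complete_case_guard():
    _, pm, _ = _fitted_cohort(seed=24)
    spec = ModelSpec(outcome="any", exposure="muscle_density",
                     adjusters=("fn_tscore", "bmi"))
    fit = fit_poisson_hazard(pm, spec)
    assert fit.names[-2:] == ["fn_tscore", "bmi"]
    pm_bad = pm.copy()
    pm_bad.loc[pm_bad.index[:5], "tscore"] = np.nan
    with pytest.raises(ValueError, match="complete-case"):
        fit_poisson_hazard(pm_bad, spec)


def test_other_muscle_adjuster_standardized():
    _, pm, _ = _fitted_cohort(seed=25)
    spec = ModelSpec(outcome="any", exposure="muscle_density",
                     adjusters=("other_muscle",))
    fit = fit_poisson_hazard(pm, spec)
    assert fit.names[-1] == "muscle_csa"
    assert fit.converged


def test_competing_joint_fit_equals_cause_specific():
    """Fracture-block coefficients of the duplicated joint fit coincide with
    the single-stratum cause-specific fit (death as censoring)."""
    cfg = replace(config.default_configs(seed=26)["HK"], n=1200,
                  frax_missing_prob=0.0)
    df = synthetic.generate_cohort(cfg)
    stacked = persontime.duplicate_for_competing(df, "any")
    spec = ModelSpec(outcome="any", exposure="muscle_density")
    joint = fit_competing(stacked, spec)
    single = fit_poisson_hazard(persontime.expand_cohort(df, "any"), spec)
    np.testing.assert_allclose(joint["any"].beta, single.beta, atol=1e-10)
    assert joint["death"].names == ["intercept", "time", "age"]
    assert joint["death"].n_events == int(np.isfinite(df["death_time"]).sum())


# ---------------------------------------------------------------------------
# gradient of risk
# ---------------------------------------------------------------------------

def test_gradient_of_risk_null_interval():
    fit = poisson.FitResult(names=["intercept", "x"],
                            beta=np.array([0.0, 0.0]),
                            cov=np.diag([1.0, 0.01]), loglik=0.0,
                            n_intervals=10, n_events=2, converged=True,
                            n_iter=3, exposure_index=1)
    gr = gradient_of_risk(fit)
    assert gr.hr == pytest.approx(1.0)
    assert gr.ci_low == pytest.approx(math.exp(-0.196), abs=1e-3)
    assert gr.ci_high == pytest.approx(math.exp(0.196), abs=1e-3)
    assert gr.p == pytest.approx(1.0)


def test_gradient_of_risk_formatting():
    # beta/se chosen so the rendered presentation is exactly "0.84 (0.72, 1.00)"
    fit = poisson.FitResult(names=["intercept", "x"],
                            beta=np.array([0.0, -0.1695]),
                            cov=np.diag([1.0, 0.0842**2]), loglik=0.0,
                            n_intervals=10, n_events=2, converged=True,
                            n_iter=3, exposure_index=1)
    assert str(gradient_of_risk(fit)) == "0.84 (0.72, 1.00)"


def test_gradient_of_risk_requires_convergence():
    fit = poisson.FitResult(names=["x"], beta=np.zeros(1), cov=np.eye(1),
                            loglik=0.0, n_intervals=1, n_events=1,
                            converged=False, n_iter=100, exposure_index=0)
    with pytest.raises(RuntimeError):
        gradient_of_risk(fit)
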