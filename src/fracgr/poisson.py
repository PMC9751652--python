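"""Poisson-process survival model on month-split person-time.

The hazard for a person-month with current time-from-baseline ``t``, current
age ``a`` and exposure-of-interest ``x`` (standardized to within-cohort SD
units) is

    λ = exp(β0 + β1·t + β2·a + β3·x + Σ βk·zk)

with optional adjusters ``zk``.  Each interval contributes
``event·log(λ·Δt) − λ·Δt`` to the log-likelihood (the exposure ``Δt`` enters
as an offset of ``log Δt``), so the partial final month is handled exactly.
Fitting is by Newton–Raphson with step-halving on the concave Poisson
log-likelihood; the covariance is the inverse observed information at the
optimum.

The association of interest is summarized as the gradient of risk,
GR = exp(β3): the hazard ratio per SD increase in the exposure, with 95%
Wald confidence interval and a two-sided normal p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "GradientOfRisk",
    "ADJUSTER_COLUMNS",
    "EXPOSURE_COLS",
    "standardize_exposure",
    "fit_poisson",
    "fit_poisson_hazard",
    "fit_competing",
    "gradient_of_risk",
]

#: Exposure name → raw column in the subject / person-month tables.
EXPOSURE_COLS = {"muscle_csa": "csa", "muscle_density": "density"}

#: Adjuster name → column.  ``other_muscle`` resolves to the standardized
#: column of the pQCT measure that is not the exposure.
ADJUSTER_COLUMNS = {
    "fn_tscore": "tscore",
    "frax_mof_wo": "frax_mof_wo",
    "frax_mof_w": "frax_mof_w",
    "prior_falls": "prior_fall",
    "bmi": "bmi",
    "other_muscle": None,
}


class SeparationError(RuntimeError):
    """The likelihood is unbounded along some coefficient direction
    (e.g. no events in a covariate stratum)."""


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the analysis grid.

    ``adjusters`` is a subset of :data:`ADJUSTER_COLUMNS`; the base model
    (age + follow-up time only) has an empty tuple.  T-score, FRAX percent
    probabilities, BMI and prior falls enter on their raw scales; the
    ``other_muscle`` adjuster is standardized identically to the exposure.
    """

    outcome: str
    exposure: str
    adjusters: tuple[str, ...] = ()
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.exposure not in EXPOSURE_COLS:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        bad = set(self.adjusters) - set(ADJUSTER_COLUMNS)
        if bad:
            raise ValueError(f"unknown adjusters {sorted(bad)}")

    @property
    def other_exposure(self) -> str:
        return ("muscle_density" if self.exposure == "muscle_csa"
                else "muscle_csa")

    def required_columns(self) -> list[str]:
        """Subject-table columns needed for complete-case analysis."""
        cols = [EXPOSURE_COLS[self.exposure]]
        for a in self.adjusters:
            cols.append(EXPOSURE_COLS[self.other_exposure] if a == "other_muscle"
                        else ADJUSTER_COLUMNS[a])
        return cols


@dataclass
class FitResult:
    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_intervals: int
    n_events: int
    converged: bool
    n_iter: int
    exposure_sd: dict[str, float] = field(default_factory=dict)
    exposure_index: int | None = None

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class GradientOfRisk:
    """Hazard ratio per SD increase in the exposure, with Wald inference."""

    exposure: str
    hr: float
    ci_low: float
    ci_high: float
    p: float

    def __str__(self) -> str:  # "0.78 (0.66, 0.91)"
        return f"{self.hr:.2f} ({self.ci_low:.2f}, {self.ci_high:.2f})"


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

def standardize_exposure(values, groups) -> tuple[np.ndarray, dict[str, float]]:
    """Standardize within cohort: (x − cohort mean) / cohort sample SD (n−1).

    Returns the standardized vector and the per-cohort SD (in raw exposure
    units, i.e. the per-SD unit of the gradient of risk).
    """
    x = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.full_like(x, np.nan)
    sds: dict[str, float] = {}
    for g in pd.unique(groups):
        mask = groups == g
        xi = x[mask]
        finite = xi[np.isfinite(xi)]
        if len(np.unique(finite)) < 2:
            raise ValueError(f"cohort {g!r}: needs ≥ 2 distinct exposure values")
        sd = float(np.std(finite, ddof=1))
        if sd == 0.0:
            raise ValueError(f"cohort {g!r}: zero exposure SD")
        out[mask] = (xi - finite.mean()) / sd
        sds[str(g)] = sd
    return out, sds


# --------------------------------------------------------------------------
# likelihood maximization
# --------------------------------------------------------------------------

def _loglik_parts(X, y, log_dt, beta):
    eta = X @ beta + log_dt
    mu = np.exp(eta)
    return float(y @ eta - mu.sum()), mu


def fit_poisson(
    X: np.ndarray,
    y: np.ndarray,
    delta_t: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FitResult:
    """Newton–Raphson MLE of the Poisson log-linear hazard.

    ``X`` is the design (including intercept), ``y`` the 0/1 event
    indicators, ``delta_t`` the interval exposures (offset ``log delta_t``).
    Convergence: relative log-likelihood change below *tol* (or score
    sup-norm below ``1e−9·max(1, n_events)``), else flagged not-converged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    dt = np.asarray(delta_t, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(y) != len(dt):
        raise ValueError("X, y, delta_t must have matching lengths")
    n_events = int(y.sum())
    if n_events < 1:
        raise ValueError("no events: Poisson hazard fit requires ≥ 1 event")
    if np.any(dt <= 0):
        raise ValueError("delta_t must be positive")
    if names is None:
        names = [f"b{j}" for j in range(X.shape[1])]

    log_dt = np.log(dt)
    beta = np.zeros(X.shape[1])
    # initialize the intercept at the crude log event rate
    const = np.all(X == X[0:1], axis=0) & (X[0] != 0)
    if const.any():
        j = int(np.nonzero(const)[0][0])
        beta[j] = np.log(n_events / dt.sum()) / X[0, j]

    ll, mu = _loglik_parts(X, y, log_dt, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = X.T @ (y - mu)
        H = X.T @ (mu[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix — design not full rank or no "
                "events in a covariate stratum"
            ) from exc
        # step-halving on the concave log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, mu_new = _loglik_parts(X, y, log_dt, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-13 * (abs(ll) + 1):
                break
            scale *= 0.5
        else:  # pragma: no cover - pathological
            break
        beta, mu = cand, mu_new
        done = abs(ll_new - ll) <= tol * (abs(ll) + 1.0)
        ll = ll_new
        if done or np.abs(X.T @ (y - mu)).max() < 1e-9 * max(1, n_events):
            converged = True
            break

    # a non-intercept log-hazard coefficient beyond ±20 (rate factor e²⁰) is
    # never a plausible optimum; it marks a likelihood drifting to infinity
    # along a separated direction.  Constant columns are exempt: with raw-
    # scale covariates (e.g. current age) the intercept legitimately absorbs
    # large offsets.
    if (~const).any() and np.abs(beta[~const]).max() > 20:
        raise SeparationError(
            "diverging coefficients — likely separation (no events in a "
            "covariate stratum)"
        )
    H = X.T @ (mu[:, None] * X)
    cov = np.linalg.inv(H)
    return FitResult(names=list(names), beta=beta, cov=cov, loglik=ll,
                     n_intervals=len(y), n_events=n_events,
                     converged=converged, n_iter=it)


def _ensure_std_columns(pm: pd.DataFrame, exposures: list[str]) -> pd.DataFrame:
    """Add ``<col>_std`` columns (within-cohort, subject-level) if absent."""
    need = [EXPOSURE_COLS[e] for e in exposures
            if f"{EXPOSURE_COLS[e]}_std" not in pm.columns]
    if not need:
        return pm
    pm = pm.copy()
    subj = pm.drop_duplicates("subject_id")
    for col in need:
        z, _ = standardize_exposure(subj[col], subj["cohort"])
        mapping = dict(zip(subj["subject_id"], z))
        pm[f"{col}_std"] = pm["subject_id"].map(mapping)
    return pm


def build_design(pm: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], dict]:
    """Design matrix, events and exposures for one person-month table.

    Columns: intercept, time since baseline, current age, standardized
    exposure, then adjusters.
    """
    xcol = EXPOSURE_COLS[spec.exposure]
    sds: dict[str, float] = {}
    if spec.standardize:
        wanted = [spec.exposure]
        if "other_muscle" in spec.adjusters:
            wanted.append(spec.other_exposure)
        pm = _ensure_std_columns(pm, wanted)
        subj = pm.drop_duplicates("subject_id")
        _, sds = standardize_exposure(subj[xcol], subj["cohort"])
        xvals = pm[f"{xcol}_std"].to_numpy(dtype=float)
    else:
        xvals = pm[xcol].to_numpy(dtype=float)

    cols = [np.ones(len(pm)), pm["t_current"].to_numpy(dtype=float),
            pm["age_current"].to_numpy(dtype=float), xvals]
    names = ["intercept", "time", "age", spec.exposure]
    for a in spec.adjusters:
        if a == "other_muscle":
            ocol = EXPOSURE_COLS[spec.other_exposure]
            col = (pm[f"{ocol}_std"] if spec.standardize else pm[ocol])
            names.append(spec.other_exposure)
        else:
            col = pm[ADJUSTER_COLUMNS[a]]
            names.append(a)
        cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariate values — apply complete-case "
                         "filtering before splitting person-time")
    return X, pm["event"].to_numpy(dtype=float), pm["delta_t"].to_numpy(dtype=float), names, sds


def fit_poisson_hazard(pm: pd.DataFrame, spec: ModelSpec, **kwargs) -> FitResult:
    """Fit the hazard model on a person-month table for one outcome stratum."""
    if "stratum" in pm.columns:
        strata = pm["stratum"].unique()
        if len(strata) > 1:
            raise ValueError("multiple strata in person-month table; use "
                             "fit_competing for duplicated data")
    X, y, dt, names, sds = build_design(pm, spec)
    fit = fit_poisson(X, y, dt, names, **kwargs)
    fit.exposure_sd = sds
    fit.exposure_index = names.index(spec.exposure)
    return fit


def fit_competing(pm: pd.DataFrame, spec: ModelSpec, **kwargs
                  ) -> dict[str, FitResult]:
    """Joint cause-specific fit on duplicated (stacked-strata) person-months.

    Each stratum gets its own coefficient block (stratum × covariate
    interactions), so the joint maximum-likelihood solution coincides with
    separate per-stratum fits; returned per stratum for convenience.
    """
    out: dict[str, FitResult] = {}
    for stratum, g in pm.groupby("stratum", sort=False):
        if stratum == "death":
            X = np.column_stack([np.ones(len(g)),
                                 g["t_current"].to_numpy(dtype=float),
                                 g["age_current"].to_numpy(dtype=float)])
            fit = fit_poisson(X, g["event"].to_numpy(dtype=float),
                              g["delta_t"].to_numpy(dtype=float),
                              ["intercept", "time", "age"], **kwargs)
        else:
            fit = fit_poisson_hazard(g, spec, **kwargs)
        out[str(stratum)] = fit
    return out


def gradient_of_risk(fit: FitResult, index: int | None = None,
                     exposure: str = "") -> GradientOfRisk:
    """GR = exp(β_exposure) with 95% Wald CI and two-sided p-value."""
    if not fit.converged:
        raise RuntimeError("cannot summarize a non-converged fit")
    j = fit.exposure_index if index is None else index
    if j is None:
        raise ValueError("fit has no recorded exposure column")
    b = float(fit.beta[j])
    se = float(np.sqrt(fit.cov[j, j]))
    z = b / se
    return GradientOfRisk(
        exposure=exposure or fit.names[j],
        hr=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.96 * se)),
        ci_high=float(np.exp(b + 1.96 * se)),
        p=max(float(2.0 * stats.norm.sf(abs(z))), np.finfo(float).tiny),
    )
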