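"""Synthetic multi-cohort person-level data.

Covariates come from a Gaussian copula with the configured moments and
correlations (FRAX probabilities get moment-matched lognormal margins).
Events are simulated in discrete time on the same 1-month grid the estimator
uses: in each month a subject still under observation fractures with
probability ``1 − exp(−λ_f/12)`` and dies with probability ``1 − exp(−λ_d/12)``,
where the all-fracture hazard ``λ_f`` is log-linear in current time, current
age and the configured per-SD covariate effects.  Within a month, fracture is
evaluated before death, so a subject who fractures and dies in the same month
contributes the fracture.  Subjects stay at risk for *further* fractures
after a non-fatal fracture (the analysis stage censors at the first
qualifying fracture per outcome); death and administrative censoring end
observation.  Each fracture is assigned a site code from the configured
site-mix categorical.

Event times are recorded at the end of their month interval, so the person-
time splitter reconstructs exactly the intervals in which the events were
generated — the generator and the fitted model share one probability space.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTINUOUS, EFFECT_COLUMNS, CohortConfig
from .outcomes import OUTCOME_ORDER, SiteMap, default_site_map, format_events, parse_events

__all__ = [
    "generate_cohort",
    "generate_study",
    "table_one",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Column order of the person-level table.
SUBJECT_COLUMNS = [
    "subject_id", "cohort", "age0", "followup", "csa", "density", "tscore",
    "bmi", "prior_fall", "frax_mof_w", "frax_mof_wo", "fracture_events",
    "death_time", "loss_time",
]

MONTH = 1.0 / 12.0


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _draw_covariates(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Correlated baseline covariates for one cohort (before missingness)."""
    k = len(CONTINUOUS)
    # eigen-factor so PSD-but-singular correlation matrices are accepted
    vals, vecs = np.linalg.eigh(cfg.corr)
    factor = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    z = rng.standard_normal((cfg.n, k)) @ factor.T
    cols = {}
    for j, name in enumerate(CONTINUOUS):
        if name.startswith("frax"):
            mean = getattr(cfg, f"{name}_mean")
            sd = getattr(cfg, f"{name}_sd")
            mu, sigma = _lognormal_params(mean, sd)
            cols[name] = np.clip(np.exp(mu + sigma * z[:, j]), None, 100.0)
        else:
            base = name[:-1] if name == "age0" else name  # age0 → age_mean
            cols[name] = getattr(cfg, f"{base}_mean") + getattr(cfg, f"{base}_sd") * z[:, j]
    df = pd.DataFrame(cols)
    df["prior_fall"] = (rng.random(cfg.n) < cfg.prior_fall_prob).astype(int)
    return df


def _linear_effect(cfg: CohortConfig, cov: pd.DataFrame) -> np.ndarray:
    """Σ β_x · x_std over the configured true effects (uses pre-mask values)."""
    eff = np.zeros(len(cov))
    for name, beta in cfg.true_log_hr.items():
        col = EFFECT_COLUMNS[name]
        if col == "prior_fall":
            eff += beta * cov[col].to_numpy(dtype=float)
        else:
            key = "age" if col == "age0" else col
            mean = getattr(cfg, f"{key}_mean")
            sd = getattr(cfg, f"{key}_sd")
            eff += beta * (cov[col].to_numpy() - mean) / sd
    return eff


def generate_cohort(cfg: CohortConfig, site_map: SiteMap | None = None) -> pd.DataFrame:
    """Simulate one cohort; fully reproducible from ``cfg.seed``.

    Returns a person-level table with one row per subject (columns
    ``SUBJECT_COLUMNS``); fracture events are serialized ``site:time`` pairs,
    missing values are NaN.
    """
    site_map = site_map or default_site_map()
    unknown = set(cfg.site_probs) - site_map.sites
    if unknown:
        raise ValueError(f"{cfg.name}: site_probs has unknown sites {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    cov = _draw_covariates(cfg, rng)
    age0 = cov["age0"].to_numpy()

    a, b = (0.5 - cfg.fu_mean) / cfg.fu_sd, (cfg.max_followup - cfg.fu_mean) / cfg.fu_sd
    followup = stats.truncnorm.rvs(a, b, loc=cfg.fu_mean, scale=cfg.fu_sd,
                                   size=cfg.n, random_state=rng)

    eff = _linear_effect(cfg, cov)
    sites = list(cfg.site_probs)
    cum = np.cumsum([cfg.site_probs[s] for s in sites])

    events: list[list[tuple[str, float]]] = [[] for _ in range(cfg.n)]
    death_time = np.full(cfg.n, np.nan)
    alive = np.ones(cfg.n, dtype=bool)

    n_months = int(math.ceil(cfg.max_followup * 12))
    for m in range(n_months):
        t0 = m * MONTH
        at_risk = alive & (followup > t0 + 1e-12)
        if not at_risk.any():
            break
        dt = np.minimum(MONTH, followup - t0)
        lam_f = np.exp(cfg.baseline_log_hazard + cfg.time_slope * t0
                       + cfg.age_slope * (age0 + t0) + eff)
        lam_d = math.exp(cfg.death_log_hazard)
        u = rng.random(cfg.n)
        v = rng.random(cfg.n)
        s = rng.random(cfg.n)
        te = t0 + dt
        fractured = at_risk & (u < -np.expm1(-lam_f * dt))
        died = at_risk & (v < -np.expm1(-lam_d * dt))
        for i in np.nonzero(fractured)[0]:
            site = sites[int(np.searchsorted(cum, s[i], side="right"))]
            events[i].append((site, float(te[i])))
        death_time[died] = te[died]
        alive &= ~died

    df = pd.DataFrame({
        "subject_id": [f"{cfg.name}-{i:05d}" for i in range(cfg.n)],
        "cohort": cfg.name,
        "age0": age0,
        "followup": followup,
        "csa": cov["csa"],
        "density": cov["density"],
        "tscore": cov["tscore"],
        "bmi": cov["bmi"],
        "prior_fall": cov["prior_fall"],
        "frax_mof_w": cov["frax_mof_w"],
        "frax_mof_wo": cov["frax_mof_wo"],
        "fracture_events": [format_events(e) for e in events],
        "death_time": death_time,
        "loss_time": np.nan,
    })
    if cfg.frax_missing_prob > 0:
        missing = rng.random(cfg.n) < cfg.frax_missing_prob
        df.loc[missing, ["frax_mof_w", "frax_mof_wo"]] = np.nan
    return df[SUBJECT_COLUMNS]


def generate_study(configs: dict[str, CohortConfig],
                   site_map: SiteMap | None = None) -> pd.DataFrame:
    """Concatenate all configured cohorts into one person-level table."""
    frames = [generate_cohort(cfg, site_map) for cfg in configs.values()]
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Descriptive table
# --------------------------------------------------------------------------

def end_of_observation(df: pd.DataFrame) -> np.ndarray:
    """min(death, loss, administrative follow-up), per subject."""
    return np.fmin(np.fmin(df["death_time"].to_numpy(dtype=float),
                           df["loss_time"].to_numpy(dtype=float)),
                   df["followup"].to_numpy(dtype=float))


def table_one(df: pd.DataFrame, site_map: SiteMap | None = None) -> pd.DataFrame:
    """Cohort-descriptive summary: n, person-years, covariate means ± SD,
    prior-fall prevalence, and per-outcome first-fracture counts and percent.

    One column per cohort; person-years use time to end of observation.
    """
    if df.empty:
        raise ValueError("empty cohort table")
    site_map = site_map or default_site_map()
    out: dict[str, dict[str, float]] = {}
    for cohort, g in df.groupby("cohort", sort=False):
        n = len(g)
        obs = end_of_observation(g)
        row: dict[str, float] = {"n": n, "person_years": float(obs.sum())}
        for col in ("age0", "bmi", "csa", "density", "tscore",
                    "frax_mof_wo", "frax_mof_w"):
            row[f"{col}_mean"] = float(g[col].mean())
            row[f"{col}_sd"] = float(g[col].std(ddof=1)) if n > 1 else float("nan")
        row["prior_fall_pct"] = 100.0 * float(g["prior_fall"].mean())
        row["fu_mean"] = float(obs.mean())
        row["fu_sd"] = float(obs.std(ddof=1)) if n > 1 else float("nan")
        parsed = [parse_events(s) for s in g["fracture_events"]]
        for outcome in OUTCOME_ORDER:
            qual = site_map.outcome_sites(outcome)
            count = sum(any(site in qual for site, _ in ev) for ev in parsed)
            row[f"{outcome}_n"] = count
            row[f"{outcome}_pct"] = 100.0 * count / n
        out[str(cohort)] = row
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# CSV schema
# --------------------------------------------------------------------------

def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Person-level CSV: one header row, events as ``site:time;…``, missing
    values as empty fields."""
    df.to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "cohort": str,
                                  "fracture_events": str})
    df["fracture_events"] = df["fracture_events"].fillna("")
    return df[SUBJECT_COLUMNS]
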