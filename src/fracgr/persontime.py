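"""Month-level person-time expansion.

Each subject's observation period is divided into intervals of 1 month
(1/12 year exactly; no calendar anchoring).  For a given fracture outcome the
time at risk is

    T = min(first qualifying fracture, loss to follow-up, death, end of follow-up)

giving ``ceil(12·T)`` intervals: full months of exposure 1/12 year plus a
possibly shorter final interval carrying its true exposure, so person-time is
conserved exactly.  The event indicator is 1 in the final interval iff T is a
qualifying fracture time.  Events on an interval boundary belong to the
earlier interval (half-open intervals ``(start, end]``); a fracture at the
same time as death counts as a fracture.

Competing mortality is handled two ways:

* the fracture-stratum expansion alone treats death as censoring, giving the
  cause-specific hazard used for the headline gradients of risk;
* :func:`duplicate_for_competing` stacks a second, death-stratum copy of the
  subject's records (time at risk to ``min(death, loss, follow-up)``, event =
  observed death) so that a joint fit over the duplicated data estimates both
  cause-specific hazards at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .outcomes import SiteMap, default_site_map, parse_events

__all__ = [
    "expand_cohort",
    "split_followup",
    "duplicate_for_competing",
    "PM_COLUMNS",
]

MONTH = 1.0 / 12.0

#: Structural columns of the person-month table (covariates follow them).
PM_COLUMNS = ["subject_id", "cohort", "stratum", "interval_index",
              "t_current", "age_current", "delta_t", "event"]

#: Subject-level covariates carried onto person-month rows when present.
DEFAULT_COVARIATES = ["csa", "density", "tscore", "bmi", "prior_fall",
                      "frax_mof_w", "frax_mof_wo"]

#: Stratum label for the mortality process in duplicated data.
DEATH = "death"


def _risk_times(df: pd.DataFrame, outcome: str, site_map: SiteMap
                ) -> tuple[np.ndarray, np.ndarray]:
    """(time at risk, event indicator) per subject for one stratum.

    ``outcome`` may be a fracture outcome name or ``"death"``.
    """
    death = df["death_time"].to_numpy(dtype=float)
    loss = df["loss_time"].to_numpy(dtype=float)
    fu = df["followup"].to_numpy(dtype=float)
    end_obs = np.fmin(np.fmin(death, loss), fu)
    if outcome == DEATH:
        event = np.isfinite(death) & (death <= np.fmin(loss, fu))
        return end_obs, event
    qual = site_map.outcome_sites(outcome)
    fx = np.full(len(df), np.nan)
    for i, text in enumerate(df["fracture_events"]):
        times = [t for site, t in parse_events(text) if site in qual]
        if times:
            fx[i] = min(times)
    event = np.isfinite(fx) & (fx <= end_obs)
    return np.fmin(fx, end_obs), event


def expand_cohort(
    df: pd.DataFrame,
    outcome: str,
    site_map: SiteMap | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Expand a person-level table into 1-month at-risk intervals.

    Parameters
    ----------
    df
        Person-level table (``synthetic.SUBJECT_COLUMNS`` schema).
    outcome
        Fracture outcome (``any``/``osteoporotic``/``MOF``/``hip``) or
        ``"death"`` for the mortality stratum.
    covariates
        Subject-level columns to carry onto the rows; defaults to every
        standard covariate (and ``*_std`` column) present in *df*.

    Subjects with non-positive time at risk contribute no intervals.
    """
    site_map = site_map or default_site_map()
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in df.columns]
        covariates += [c for c in df.columns if c.endswith("_std")]

    T, event = _risk_times(df, outcome, site_map)
    keep = T > 1e-12
    df = df.loc[keep]
    T, event = T[keep], event[keep]

    # ceil with a guard so times that are exact month multiples (up to float
    # noise) do not spawn a zero-length trailing interval
    n_int = np.ceil(T * 12.0 - 1e-9).astype(int)
    starts = np.concatenate(([0], np.cumsum(n_int)))
    total = int(starts[-1])
    rep = np.repeat(np.arange(len(df)), n_int)
    interval = np.arange(total) - np.repeat(starts[:-1], n_int)

    delta_t = np.full(total, MONTH)
    last = starts[1:] - 1
    delta_t[last] = T - (n_int - 1) * MONTH
    ev = np.zeros(total, dtype=int)
    ev[last] = event.astype(int)

    t_cur = interval * MONTH
    out = pd.DataFrame({
        "subject_id": df["subject_id"].to_numpy()[rep],
        "cohort": df["cohort"].to_numpy()[rep],
        "stratum": outcome,
        "interval_index": interval,
        "t_current": t_cur,
        "age_current": df["age0"].to_numpy(dtype=float)[rep] + t_cur,
        "delta_t": delta_t,
        "event": ev,
    })
    for c in covariates:
        out[c] = df[c].to_numpy()[rep]
    return out


def split_followup(subject: pd.Series | dict, outcome: str,
                   site_map: SiteMap | None = None) -> pd.DataFrame:
    """Person-month intervals for a single subject (fracture stratum)."""
    return expand_cohort(pd.DataFrame([dict(subject)]), outcome, site_map)


def duplicate_for_competing(
    df: pd.DataFrame | pd.Series | dict,
    outcome: str,
    site_map: SiteMap | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Stacked fracture-stratum + death-stratum person-months.

    The duplicated (data-duplication) layout lets one joint Poisson fit with
    stratum-specific coefficient blocks estimate the cause-specific fracture
    and mortality hazards simultaneously; fitting the fracture block alone is
    identical to treating death as censoring.
    """
    if not isinstance(df, pd.DataFrame):
        df = pd.DataFrame([dict(df)])
    frac = expand_cohort(df, outcome, site_map, covariates)
    death = expand_cohort(df, DEATH, site_map, covariates)
    return pd.concat([frac, death], ignore_index=True)
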