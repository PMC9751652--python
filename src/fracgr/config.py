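"""Cohort configuration for the synthetic multi-cohort generator.

A :class:`CohortConfig` fully determines one simulated cohort: baseline
covariate moments and correlations, the follow-up distribution, the
cause-specific event hazards, and the per-SD exposure effects.  The packaged
defaults (:func:`default_configs`) describe three cohorts of older,
community-dwelling men — labelled ``HK``, ``SW`` and ``US`` — whose covariate
moments, person-years, follow-up and nested fracture-outcome frequencies match
the published baseline table of the three-country calf-pQCT fracture study
this package models (e.g. HK: n = 1662, muscle density 77.0 ± 3.6 mg/cm³,
47 hip fractures over 13 541.8 person-years).

Two calibrations are solved numerically when defaults are built:

* the intercept of the all-fracture log-hazard, so the expected crude event
  rate matches the observed events/person-years, accounting for the lognormal
  mean of the covariate-dependent part of the hazard;
* the administrative follow-up mean, so the *observed* mean follow-up
  E[min(death time, administrative censoring)] matches person-years / n —
  published follow-up already reflects death truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import integrate, optimize, stats

__all__ = [
    "CohortConfig",
    "ConfigError",
    "CONTINUOUS",
    "EFFECT_COLUMNS",
    "DEFAULT_CORR",
    "default_configs",
    "load_configs",
    "dump_configs",
]

#: Continuous covariates drawn from the correlated Gaussian copula, in the
#: order used by the correlation matrix.
CONTINUOUS: tuple[str, ...] = (
    "age0", "bmi", "csa", "density", "tscore", "frax_mof_wo", "frax_mof_w",
)

#: Effect names accepted in ``true_log_hr`` → subject-table column.
EFFECT_COLUMNS: dict[str, str] = {
    "muscle_csa": "csa",
    "muscle_density": "density",
    "fn_tscore": "tscore",
    "bmi": "bmi",
    "frax_mof_wo": "frax_mof_wo",
    "frax_mof_w": "frax_mof_w",
    "prior_falls": "prior_fall",
}

# Assumed covariate correlation structure, identical across cohorts (the
# source study does not report correlations; see docs/methods.md).  Order is
# CONTINUOUS.  Positive definite: eigenvalues in [0.049, 2.57].
DEFAULT_CORR: np.ndarray = np.array([
    #  age    bmi    csa    dens   tsc    frax_wo frax_w
    [1.00, -0.05, -0.20, -0.25, -0.10,  0.45,  0.40],   # age0
    [-0.05, 1.00,  0.45, -0.15,  0.25, -0.10, -0.15],   # bmi
    [-0.20, 0.45,  1.00,  0.10,  0.30, -0.10, -0.20],   # csa
    [-0.25, -0.15, 0.10,  1.00,  0.10, -0.10, -0.10],   # density
    [-0.10, 0.25,  0.30,  0.10,  1.00, -0.15, -0.55],   # tscore
    [0.45, -0.10, -0.10, -0.10, -0.15,  1.00,  0.85],   # frax_mof_wo
    [0.40, -0.15, -0.20, -0.10, -0.55,  0.85,  1.00],   # frax_mof_w
])


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Generator settings for one synthetic cohort.

    Continuous covariates are Gaussian with the given means/SDs except the two
    FRAX probabilities, which get lognormal margins (moment-matched, clipped
    to (0, 100] percent) through a Gaussian copula with correlation ``corr``.

    Hazards are log-linear.  The all-fracture hazard per person-year is
    ``exp(baseline_log_hazard + time_slope*t + age_slope*age(t) + Σ β_x·x_std)``
    where ``x_std`` is the covariate standardized by its *configured* mean/SD
    and β_x comes from ``true_log_hr`` (per-SD log hazard ratios; the
    ``prior_falls`` effect, if any, is per unit of the 0/1 indicator).
    Mortality is a competing flat hazard ``exp(death_log_hazard)``.
    """

    name: str
    n: int
    # covariate moments
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    csa_mean: float
    csa_sd: float
    density_mean: float
    density_sd: float
    tscore_mean: float
    tscore_sd: float
    frax_mof_wo_mean: float
    frax_mof_wo_sd: float
    frax_mof_w_mean: float
    frax_mof_w_sd: float
    prior_fall_prob: float
    frax_missing_prob: float = 0.0
    # follow-up (administrative censoring), truncated normal on (0.5, max_followup]
    fu_mean: float = 8.0
    fu_sd: float = 2.0
    max_followup: float = 12.0
    # hazards
    baseline_log_hazard: float = -4.5     # all-fracture intercept, per person-year
    time_slope: float = 0.0               # per year since baseline
    age_slope: float = 0.0                # per year of current age
    death_log_hazard: float = -4.0        # mortality intercept, per person-year
    true_log_hr: dict[str, float] = field(default_factory=dict)
    site_probs: dict[str, float] = field(default_factory=lambda: {"hip": 1.0})
    corr: np.ndarray = field(default_factory=lambda: DEFAULT_CORR.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"{self.name}: n must be ≥ 1")
        for f in ("age_sd", "bmi_sd", "csa_sd", "density_sd", "tscore_sd",
                  "frax_mof_wo_sd", "frax_mof_w_sd", "fu_sd"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{self.name}: {f} must be > 0")
        for f in ("prior_fall_prob", "frax_missing_prob"):
            p = getattr(self, f)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{self.name}: {f} must be in [0, 1]")
        if self.max_followup <= 0:
            raise ConfigError(f"{self.name}: max_followup must be > 0")
        k = len(CONTINUOUS)
        if self.corr.shape != (k, k):
            raise ConfigError(f"{self.name}: corr must be {k}×{k} over {CONTINUOUS}")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise ConfigError(f"{self.name}: corr must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-12):
            raise ConfigError(f"{self.name}: corr must have unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() < -1e-8:
            raise ConfigError(f"{self.name}: corr is not positive semi-definite")
        bad = set(self.true_log_hr) - set(EFFECT_COLUMNS)
        if bad:
            raise ConfigError(f"{self.name}: unknown effect names {sorted(bad)}")
        if self.site_probs:
            total = sum(self.site_probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-8):
                raise ConfigError(f"{self.name}: site_probs sum to {total}, not 1")


# --------------------------------------------------------------------------
# Calibrated three-cohort defaults
# --------------------------------------------------------------------------

# Published baseline characteristics of the three cohorts: n, total
# person-years, covariate means±SDs, FRAX-complete counts, prior-fall
# prevalence, follow-up mean±SD and nested fracture counts
# (any ⊇ osteoporotic ⊇ MOF ⊇ hip).  Death rates are assumptions
# (healthy-volunteer mortality for men of each cohort's mean age).
_BASELINE = {
    "HK": dict(n=1662, py=13541.8, age=(73.9, 4.9), bmi=(23.4, 3.1),
               csa=(35.4, 7.0), dens=(77.0, 3.6), tsc=(-1.41, 0.91),
               frax_wo=(7.9, 3.4), frax_w=(7.2, 3.7), n_frax=1382,
               fall=0.173, fu=(8.1, 2.3), max_fu=12.0, death_rate=0.020,
               events=dict(any=161, osteoporotic=125, MOF=94, hip=47)),
    "SW": dict(n=1521, py=8057.5, age=(79.5, 3.4), bmi=(26.2, 3.3),
               csa=(38.9, 7.4), dens=(69.6, 3.7), tsc=(-0.92, 1.02),
               frax_wo=(15.7, 6.7), frax_w=(11.8, 6.7), n_frax=976,
               fall=0.132, fu=(5.3, 2.0), max_fu=9.0, death_rate=0.035,
               events=dict(any=238, osteoporotic=206, MOF=180, hip=78)),
    "US": dict(n=991, py=7777.5, age=(77.0, 5.1), bmi=(27.8, 3.7),
               csa=(75.5, 11.8), dens=(70.5, 4.6), tsc=(-0.53, 1.06),
               frax_wo=(10.6, 5.0), frax_w=(8.2, 4.3), n_frax=478,
               fall=0.232, fu=(7.8, 2.2), max_fu=12.0, death_rate=0.027,
               events=dict(any=137, osteoporotic=103, MOF=68, hip=31)),
}

# Fixed within-category site splits used to turn the nested outcome counts
# into a flat site-mix categorical.
_MOF_NONHIP = {"wrist": 0.50, "vertebra": 0.35, "shoulder": 0.15}
_OST_NONMOF = {"ribs": 0.40, "pelvis": 0.20, "tibia": 0.20,
               "clavicle": 0.10, "humerus": 0.10}
_ANY_NONOST = {"foot": 0.40, "hand": 0.25, "skull_face": 0.20, "fingers": 0.15}

# Default data-generating effects (per within-cohort SD): greater muscle
# density and greater femoral-neck BMD T-score each lower fracture hazard;
# muscle CSA has NO direct effect and associates with fracture only through
# its correlation with T-score — mirroring the attenuation pattern the
# analysis is designed to detect.
_DEFAULT_EFFECTS = {"muscle_density": math.log(0.80), "fn_tscore": math.log(0.70)}


def _site_probs(events: dict[str, int]) -> dict[str, float]:
    any_n = events["any"]
    shares = {
        "hip": events["hip"] / any_n,
    }
    mof_extra = (events["MOF"] - events["hip"]) / any_n
    ost_extra = (events["osteoporotic"] - events["MOF"]) / any_n
    non_ost = (any_n - events["osteoporotic"]) / any_n
    for table, mass in ((_MOF_NONHIP, mof_extra), (_OST_NONMOF, ost_extra),
                        (_ANY_NONOST, non_ost)):
        for site, w in table.items():
            shares[site] = shares.get(site, 0.0) + w * mass
    total = sum(shares.values())
    return {s: p / total for s, p in shares.items()}


def _fu_mean_for_observed(target: float, fu_sd: float, lo: float, hi: float,
                          death_rate: float) -> float:
    """Administrative-FU mean whose observed E[min(death, FU)] hits *target*."""

    def observed(m: float) -> float:
        a, b = (lo - m) / fu_sd, (hi - m) / fu_sd
        f = stats.truncnorm(a, b, loc=m, scale=fu_sd)
        val, _ = integrate.quad(lambda t: math.exp(-death_rate * t) * f.sf(t),
                                0.0, hi, limit=200)
        return val

    return optimize.brentq(lambda m: observed(m) - target,
                           0.6 * target, hi - 1e-6, xtol=1e-8)


def _followup_growth_factor(growth: float, fu_mean: float, fu_sd: float,
                            lo: float, hi: float, death_rate: float) -> float:
    """Person-time-weighted mean of exp(growth·t) over observed follow-up.

    With observed follow-up T = min(death, administrative censoring), this is
    E[∫₀ᵀ e^{g·t} dt] / E[T]; it converts a hazard evaluated at baseline into
    the crude whole-follow-up rate when the log-hazard grows linearly in time
    (through the age and time slopes).
    """
    if abs(growth) < 1e-12:
        return 1.0
    a, b = (lo - fu_mean) / fu_sd, (hi - fu_mean) / fu_sd
    f = stats.truncnorm(a, b, loc=fu_mean, scale=fu_sd)

    def surv(t: float) -> float:
        return math.exp(-death_rate * t) * f.sf(t)

    num, _ = integrate.quad(lambda t: math.exp(growth * t) * surv(t), 0.0, hi,
                            limit=200)
    den, _ = integrate.quad(surv, 0.0, hi, limit=200)
    return num / den


def _intercept_for_rate(rate: float, cfg: CohortConfig) -> float:
    """All-fracture intercept matching an expected crude *rate* per person-year.

    E[exp(lin. predictor)] over covariates is exp(mean + var/2) for the
    Gaussian part; the binary prior-falls effect, if present, contributes its
    own moment-generating factor; aging during follow-up contributes the
    person-time-weighted growth factor of exp((age_slope+time_slope)·t).
    """
    w = np.zeros(len(CONTINUOUS))
    idx = {c: i for i, c in enumerate(CONTINUOUS)}
    w[idx["age0"]] += cfg.age_slope * cfg.age_sd
    mean_extra = cfg.age_slope * cfg.age_mean
    for name, beta in cfg.true_log_hr.items():
        col = EFFECT_COLUMNS[name]
        if col == "prior_fall":
            p = cfg.prior_fall_prob
            mean_extra += math.log((1 - p) + p * math.exp(beta))
        else:
            w[idx[col]] += beta
    var = float(w @ cfg.corr @ w)
    growth = _followup_growth_factor(
        cfg.age_slope + cfg.time_slope, cfg.fu_mean, cfg.fu_sd, 0.5,
        cfg.max_followup, math.exp(cfg.death_log_hazard))
    return math.log(rate) - mean_extra - 0.5 * var - math.log(growth)


def default_configs(
    seed: int = 0,
    n: int | None = None,
    true_log_hr: dict[str, float] | None = None,
    frax_missing: bool = True,
) -> dict[str, CohortConfig]:
    """The calibrated three-cohort defaults.

    Parameters
    ----------
    seed
        Master seed; each cohort derives a sub-stream from (seed, index).
    n
        Override the per-cohort sample size (default: published n).
    true_log_hr
        Override the data-generating per-SD effects (default: density 0.80,
        T-score 0.70 per SD, no direct CSA effect).
    frax_missing
        Emulate the observed FRAX-complete subset sizes (else no missingness).
    """
    effects = _DEFAULT_EFFECTS if true_log_hr is None else true_log_hr
    out: dict[str, CohortConfig] = {}
    for i, (name, t) in enumerate(_BASELINE.items()):
        obs_fu = t["py"] / t["n"]
        fu_mean = _fu_mean_for_observed(obs_fu, t["fu"][1], 0.5, t["max_fu"],
                                        t["death_rate"])
        cfg = CohortConfig(
            name=name,
            n=n if n is not None else t["n"],
            age_mean=t["age"][0], age_sd=t["age"][1],
            bmi_mean=t["bmi"][0], bmi_sd=t["bmi"][1],
            csa_mean=t["csa"][0], csa_sd=t["csa"][1],
            density_mean=t["dens"][0], density_sd=t["dens"][1],
            tscore_mean=t["tsc"][0], tscore_sd=t["tsc"][1],
            frax_mof_wo_mean=t["frax_wo"][0], frax_mof_wo_sd=t["frax_wo"][1],
            frax_mof_w_mean=t["frax_w"][0], frax_mof_w_sd=t["frax_w"][1],
            prior_fall_prob=t["fall"],
            frax_missing_prob=(1.0 - t["n_frax"] / t["n"]) if frax_missing else 0.0,
            fu_mean=fu_mean, fu_sd=t["fu"][1], max_followup=t["max_fu"],
            age_slope=0.07,
            death_log_hazard=math.log(t["death_rate"]),
            true_log_hr=dict(effects),
            site_probs=_site_probs(t["events"]),
            seed=seed * 1000 + i,
        )
        cfg.baseline_log_hazard = _intercept_for_rate(t["events"]["any"] / t["py"], cfg)
        out[name] = cfg
    return out


# --------------------------------------------------------------------------
# YAML round-trip
# --------------------------------------------------------------------------

def dump_configs(configs: dict[str, CohortConfig], path: str | Path) -> None:
    """Write configs to a YAML document (one mapping per cohort)."""
    doc = {}
    for name, cfg in configs.items():
        d = {k: v for k, v in vars(cfg).items() if k != "corr"}
        d["corr"] = cfg.corr.tolist()
        doc[name] = d
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_configs(path: str | Path, seed: int | None = None) -> dict[str, CohortConfig]:
    """Read a YAML config written by :func:`dump_configs`.

    Each cohort mapping may omit any field; omissions fall back to the
    calibrated default for that cohort name (or, for unknown names, to the
    dataclass defaults with the given overrides).  ``seed`` overrides the
    master seed stream.
    """
    doc = yaml.safe_load(Path(path).read_text())
    defaults = default_configs(seed=seed if seed is not None else 0)
    out: dict[str, CohortConfig] = {}
    for i, (name, fields_) in enumerate(doc.items()):
        fields_ = dict(fields_ or {})
        fields_.pop("name", None)
        if "corr" in fields_:
            fields_["corr"] = np.asarray(fields_["corr"], dtype=float)
        if name in defaults:
            cfg = replace(defaults[name], **fields_)
        else:
            cfg = CohortConfig(name=name, **fields_)
        if seed is not None:
            cfg = replace(cfg, seed=seed * 1000 + i)
        out[name] = cfg
    return out
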