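"""Inverse-variance pooling of per-cohort log hazard ratios.

The headline synthesis is fixed-effects: each cohort's coefficient β_i is
weighted by w_i = 1/se_i², the pooled coefficient is the weighted mean, and
the pooled risk ratio is its exponential.  Heterogeneity is summarized by
Cochran's Q = Σ w_i (β_i − β̄)² and I² = max(0, (Q − (k−1))/Q)·100 — the
percentage of between-cohort variability beyond chance.  A
DerSimonian–Laird random-effects pooling is provided as a labelled
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "pool_fixed_effects", "pool_random_effects"]


@dataclass
class MetaResult:
    """Pooled per-SD log hazard ratio with heterogeneity diagnostics."""

    beta: float          # pooled log hazard ratio per SD
    se: float
    hr: float            # pooled gradient of risk, exp(beta)
    ci_low: float
    ci_high: float
    p: float             # two-sided Wald p-value
    q: float             # Cochran Q
    i2: float            # percent
    k: int               # number of cohorts
    method: str = "fixed"

    def __str__(self) -> str:
        return (f"{self.hr:.2f} ({self.ci_low:.2f}, {self.ci_high:.2f})"
                f" [k={self.k}, I²={self.i2:.0f}%]")


def _check(estimates) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    beta = np.asarray([b for b, _ in estimates], dtype=float)
    se = np.asarray([s for _, s in estimates], dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)) or not np.all(np.isfinite(beta)):
        raise ValueError("all estimates need finite beta and se > 0")
    return beta, se


def _result(beta_p: float, se_p: float, q: float, i2: float, k: int,
            method: str) -> MetaResult:
    z = beta_p / se_p
    return MetaResult(
        beta=beta_p, se=se_p, hr=float(np.exp(beta_p)),
        ci_low=float(np.exp(beta_p - 1.96 * se_p)),
        ci_high=float(np.exp(beta_p + 1.96 * se_p)),
        p=max(float(2.0 * stats.norm.sf(abs(z))), np.finfo(float).tiny),
        q=q, i2=i2, k=k, method=method,
    )


def pool_fixed_effects(estimates: list[tuple[float, float]]) -> MetaResult:
    """Fixed-effects inverse-variance pooling of (beta, se) pairs.

    The risk ratio is e^(weighted mean coefficient); Q and I² quantify
    heterogeneity (I² = 0 when Q = 0, including the single-study case).
    """
    beta, se = _check(estimates)
    w = 1.0 / se**2
    beta_p = float(w @ beta / w.sum())
    se_p = float(w.sum() ** -0.5)
    q = float(w @ (beta - beta_p) ** 2)
    k = len(beta)
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return _result(beta_p, se_p, q, i2, k, "fixed")


def pool_random_effects(estimates: list[tuple[float, float]]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling (sensitivity output).

    The between-cohort variance τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))
    inflates each cohort's variance before re-weighting.
    """
    beta, se = _check(estimates)
    fixed = pool_fixed_effects(estimates)
    k = len(beta)
    w = 1.0 / se**2
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = 0.0 if denom <= 0 else max(0.0, (fixed.q - (k - 1)) / denom)
    w_re = 1.0 / (se**2 + tau2)
    beta_p = float(w_re @ beta / w_re.sum())
    se_p = float(w_re.sum() ** -0.5)
    return _result(beta_p, se_p, fixed.q, fixed.i2, k, "random")
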