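"""Synthetic cohort generator: trivial cases, closed-form survival,
moment recovery against the calibrated baseline table, determinism."""

import math

import numpy as np
import pytest
from dataclasses import replace

from fracgr import config, synthetic
from fracgr.outcomes import parse_events


def _plain_config(**kw):
    """HK-like config stripped of covariate effects and age/time slopes."""
    base = config.default_configs(seed=3)["HK"]
    fields = dict(age_slope=0.0, time_slope=0.0, true_log_hr={},
                  frax_missing_prob=0.0)
    fields.update(kw)
    return replace(base, **fields)


def test_zero_hazard_yields_no_events():
    cfg = _plain_config(n=500, baseline_log_hazard=-np.inf,
                        death_log_hazard=-np.inf)
    df = synthetic.generate_cohort(cfg)
    assert (df["fracture_events"] == "").all()
    assert df["death_time"].isna().all()


def test_constant_hazard_matches_exponential_survival():
    """With a flat hazard e^-4/yr, no death and 5 y follow-up, the fraction
    of subjects with ≥1 event is 1 − exp(−5·e^−4) (exact for the discrete
    monthly scheme), within 3 Monte-Carlo SEs."""
    lam = math.exp(-4.0)
    cfg = _plain_config(n=20000, baseline_log_hazard=-4.0,
                        death_log_hazard=-np.inf,
                        fu_mean=5.0, fu_sd=1e-9, max_followup=5.0)
    df = synthetic.generate_cohort(cfg)
    p_true = -math.expm1(-5.0 * lam)
    p_obs = (df["fracture_events"] != "").mean()
    se = math.sqrt(p_true * (1 - p_true) / cfg.n)
    assert abs(p_obs - p_true) < 3 * se
    # empirical survival of the first-event time tracks exp(-λt)
    first = np.array([min(t for _, t in parse_events(s)) if s else np.inf
                      for s in df["fracture_events"]])
    for t in (1.0, 2.5, 4.0):
        s_true = math.exp(-lam * t)
        s_obs = (first > t + 1e-12).mean()
        se_t = math.sqrt(s_true * (1 - s_true) / cfg.n)
        assert abs(s_obs - s_true) < 3 * se_t


def test_covariate_moment_recovery():
    """HK defaults at n = 10⁴: density 77.0 ± 3.6, age 73.9, within 3 SEs."""
    cfg = replace(config.default_configs(seed=5)["HK"], n=10000)
    df = synthetic.generate_cohort(cfg)
    n = cfg.n
    assert abs(df["density"].mean() - 77.0) < 3 * 3.6 / math.sqrt(n)
    assert abs(df["density"].std(ddof=1) - 3.6) < 3 * 3.6 / math.sqrt(2 * n)
    assert abs(df["age0"].mean() - 73.9) < 3 * 4.9 / math.sqrt(n)
    assert abs(df["bmi"].std(ddof=1) - 3.1) < 3 * 3.1 / math.sqrt(2 * n)
    # lognormal FRAX margins are moment-matched too
    frax = df["frax_mof_w"].dropna()
    assert abs(frax.mean() - 7.2) < 4 * 3.7 / math.sqrt(len(frax))
    assert ((frax > 0) & (frax <= 100)).all()


def test_correlation_structure_recovered():
    cfg = replace(config.default_configs(seed=6)["HK"], n=20000,
                  frax_missing_prob=0.0)
    df = synthetic.generate_cohort(cfg)
    r = np.corrcoef(df["csa"], df["tscore"])[0, 1]
    assert abs(r - 0.30) < 0.03
    r2 = np.corrcoef(df["age0"], df["density"])[0, 1]
    assert abs(r2 - (-0.25)) < 0.03


def test_determinism_byte_identical():
    cfg = _plain_config(n=200)
    a = synthetic.generate_cohort(cfg).to_csv(index=False)
    b = synthetic.generate_cohort(cfg).to_csv(index=False)
    assert a == b
    c = synthetic.generate_cohort(replace(cfg, seed=cfg.seed + 1)).to_csv(index=False)
    assert a != c


def test_no_events_after_death_or_censoring(small_study):
    for _, row in small_study.iterrows():
        end = np.nanmin([row["death_time"], row["loss_time"], row["followup"]])
        for _, t in parse_events(row["fracture_events"]):
            assert 0 < t <= end + 1e-9
        if np.isfinite(row["death_time"]):
            assert row["death_time"] <= row["followup"] + 1e-9


def test_invalid_corr_rejected():
    bad = np.eye(len(config.CONTINUOUS))
    bad[0, 1] = bad[1, 0] = 0.99
    bad[0, 2] = bad[2, 0] = 0.99
    bad[1, 2] = bad[2, 1] = -0.99
    with pytest.raises(config.ConfigError, match="positive semi-definite"):
        replace(config.default_configs()["HK"], corr=bad)


# ---------------------------------------------------------------------------
# descriptive table
# ---------------------------------------------------------------------------

def test_table_one_single_subject():
    from .conftest import make_subject
    import pandas as pd

    df = pd.DataFrame([make_subject(followup=2.0)])
    t = synthetic.table_one(df)
    assert t.loc["person_years", "HK"] == pytest.approx(2.0)
    for outcome in ("any", "osteoporotic", "MOF", "hip"):
        assert t.loc[f"{outcome}_n", "HK"] == 0


def test_table_one_event_percentages():
    from .conftest import make_subject
    import pandas as pd

    df = pd.DataFrame([make_subject(subject_id="a", fracture_events="hip:1.5"),
                       make_subject(subject_id="b")])
    t = synthetic.table_one(df)
    assert t.loc["hip_n", "HK"] == 1
    assert t.loc["hip_pct", "HK"] == pytest.approx(50.0)


def test_table_one_person_years_match_calibration():
    """Full-size HK cohort: total person-years ≈ n × target observed
    follow-up (the published 13 541.8 person-years) within 3 sampling SEs."""
    cfg = config.default_configs(seed=9)["HK"]
    df = synthetic.generate_cohort(cfg)
    t = synthetic.table_one(df)
    total = t.loc["person_years", "HK"]
    se = 2.3 * math.sqrt(cfg.n)  # SD of per-subject follow-up ≈ 2.3 y
    assert abs(total - 13541.8) < 3 * se


def test_table_one_empty_errors():
    import pandas as pd

    with pytest.raises(ValueError):
        synthetic.table_one(pd.DataFrame(columns=synthetic.SUBJECT_COLUMNS))


def test_csv_roundtrip(tmp_path, small_study):
    path = tmp_path / "cohorts.csv"
    synthetic.write_cohort_csv(small_study, path)
    back = synthetic.read_cohort_csv(path)
    assert list(back.columns) == synthetic.SUBJECT_COLUMNS
    assert len(back) == len(small_study)
    assert (back["fracture_events"] == small_study["fracture_events"]).all()
    np.testing.assert_allclose(back["density"], small_study["density"],
                               rtol=1e-9)
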