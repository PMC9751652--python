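import math

import pytest

from fracgr import config, synthetic


@pytest.fixture(scope="session")
def site_map():
    from fracgr.outcomes import default_site_map

    return default_site_map()


@pytest.fixture(scope="session")
def small_configs():
    """Three Table-calibrated cohorts scaled down for fast tests."""
    return config.default_configs(seed=11, n=400)


@pytest.fixture(scope="session")
def small_study(small_configs):
    return synthetic.generate_study(small_configs)


def make_subject(**kw):
    """A minimal person-level row; override any field."""
    row = dict(
        subject_id="s0", cohort="HK", age0=74.0, followup=5.0,
        csa=35.0, density=77.0, tscore=-1.4, bmi=23.0, prior_fall=0,
        frax_mof_w=7.0, frax_mof_wo=8.0, fracture_events="",
        death_time=math.nan, loss_time=math.nan,
    )
    row.update(kw)
    return row
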