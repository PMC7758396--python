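import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dscore as d

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return d.default_config(seed=11)


@pytest.fixture(scope="session")
def small_cfg():
    # small but QDA-fittable cohort: 60 + 30 patients
    return d.default_config(seed=11).with_(n_group_a=60, n_group_b=30)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return d.simulate_profiles(small_cfg)


@pytest.fixture(scope="session")
def fitted(small_cohort):
    return d.fit_stratifier(small_cohort, d.PANEL14)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def cohort_from_counts(tp, fp, fn, tn, positive="higher_risk", negative="lower_risk"):
    """Expand a 2x2 table into aligned calls/truth label lists."""
    calls = [positive] * tp + [negative] * fn + [positive] * fp + [negative] * tn
    truth = [positive] * (tp + fn) + [negative] * (fp + tn)
    return calls, truth


@pytest.fixture(scope="session")
def ct_table_df(small_cfg, small_cohort):
    return d.profiles_to_raw_ct(small_cohort, small_cfg)
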