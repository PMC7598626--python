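import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import implantfit as iff
from implantfit.cohort import Cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_cohort(df_dict, **kwargs) -> Cohort:
    return Cohort(pd.DataFrame(df_dict), **kwargs)


@pytest.fixture()
def hand_cohort() -> Cohort:
    """Four patients with easy-to-verify numbers."""
    return make_cohort(
        {
            "patient_id": ["a", "b", "c", "d"],
            "v_healthy_pre": [200.0, 300.0, 400.0, 500.0],
            "v_affected_pre": [180.0, 310.0, 350.0, 480.0],
            "w_mast": [190.0, 280.0, 360.0, 450.0],
            "i_inserted": [210.0, 270.0, 330.0, 405.0],
            "v_recon_post": [215.0, 295.0, 390.0, 520.0],
            "v_healthy_post": [205.0, 305.0, 405.0, 495.0],
        }
    )


@pytest.fixture(scope="session")
def large_cohort():
    """One n = 100 000 default-calibration cohort shared across the suite."""
    config = iff.default_calibration(n=100_000, seed=123)
    return iff.generate_cohort(config)


@pytest.fixture(scope="session")
def large_corrected(large_cohort):
    cohort, _ = large_cohort
    corrected, result = iff.compute_ideal_cohort(cohort, method="beta_corrected")
    return corrected, result
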