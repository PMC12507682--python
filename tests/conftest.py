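import numpy as np
import pandas as pd
import pytest

from lipoflux import GroundTruth, NoiseSpec, TimeCourse, build_model, gen_timecourse


@pytest.fixture
def pm_er_model():
    return build_model("pm_er")


@pytest.fixture
def pm_er_truth():
    return GroundTruth(
        rate_params={"k_PM_ER": 0.2, "k_ER_PM": 0.1},
        initial_state={"PM": 1.0},
        seed=11,
    )


@pytest.fixture
def noiseless_pm_er_tc(pm_er_model, pm_er_truth):
    return gen_timecourse(pm_er_truth, pm_er_model, NoiseSpec(sd_fraction=0.0))


@pytest.fixture
def noisy_pm_er_tc(pm_er_model, pm_er_truth):
    return gen_timecourse(pm_er_truth, pm_er_model, NoiseSpec(sd_fraction=0.02))


def make_timecourse(rows):
    """Build a TimeCourse from (time, organelle, mean, sd, n) tuples."""
    return TimeCourse(pd.DataFrame(rows, columns=["time_min", "organelle", "mean", "sd", "n"]))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
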