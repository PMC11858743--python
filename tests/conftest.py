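import datetime as dt

import numpy as np
import pytest

from sexdem import SimulationConfig, simulate_hormone_profiles, simulate_population
from sexdem.simulate import PregnancyRecord


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def population(default_config):
    return simulate_population(default_config)


@pytest.fixture(scope="session")
def separated_pregnancies():
    """40 labelled pregnancies under the well-separated hormone regime."""
    rng = np.random.default_rng(42)
    pregs = []
    for i in range(40):
        sex = "male" if rng.uniform() < 0.5 else "female"
        pregs.append(
            PregnancyRecord(
                mother_id=f"M{i:03d}",
                birth_date=dt.date(2016 + i % 7, 9, 1 + i % 28),
                true_fetal_sex=sex,
                observed_sex=sex,
                sexing_mode="visual",
            )
        )
    return pregs


@pytest.fixture(scope="session")
def separated_hormones(separated_pregnancies):
    return simulate_hormone_profiles(separated_pregnancies, SimulationConfig(seed=42))
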