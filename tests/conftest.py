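import numpy as np
import pytest

from vslqaly.economic_data import EconomicProfile, LifeTable, PopulationDistribution, SurvivalModel
from vslqaly.pipeline import StudyConfig, run_study, synthetic_inputs
from vslqaly.qol_scenarios import QoLTrajectory


@pytest.fixture(scope="session")
def toy_table():
    """Five-age life table with simple survivor ratios."""
    return LifeTable(np.arange(5.0), np.array([100.0, 80.0, 60.0, 30.0, 0.0]), 4)


@pytest.fixture(scope="session")
def synth_inputs():
    """The shipped japan-like synthetic inputs (deterministic)."""
    return synthetic_inputs()


@pytest.fixture(scope="session")
def base_study(synth_inputs):
    """Full baseline study on the synthetic preset, shared across tests."""
    return run_study(synth_inputs, StudyConfig())


def flat_trajectory(a_max=4, name="flat"):
    ages = np.arange(0.0, a_max + 1)
    ones = np.ones_like(ages)
    return QoLTrajectory(name, ages, ones.copy(), ones.copy(), None)


@pytest.fixture
def toy_setup(toy_table):
    """Survival + constant-money profile + perfect health on a 5-age grid."""
    surv = SurvivalModel(toy_table)
    ages = np.arange(5.0)
    profile = EconomicProfile(ages, np.full(5, 6.0), np.full(5, 4.0))
    return surv, profile, flat_trajectory(4)
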