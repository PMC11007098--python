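import numpy as np
import pytest

import survcea as sc


@pytest.fixture(scope="session")
def base_inputs() -> sc.EconomicInputs:
    return sc.default_inputs()


@pytest.fixture(scope="session")
def base_result(base_inputs):
    return sc.base_case(base_inputs)


@pytest.fixture(scope="session")
def base_traces(base_inputs):
    s = base_inputs.survival
    active = sc.run_cohort(base_inputs.spec, s.dfs_active, s.os_active, base_inputs.life_table)
    control = sc.run_cohort(base_inputs.spec, s.dfs_control, s.os_control, base_inputs.life_table)
    return active, control


@pytest.fixture(scope="session")
def psa_samples(base_inputs):
    return sc.run_psa(base_inputs)


@pytest.fixture(scope="session")
def loglogistic_dfs() -> sc.ParametricSurvival:
    """The active-arm DFS extrapolation curve."""
    return sc.ParametricSurvival("loglogistic", {"shape": 1.63351, "scale": 112.73457})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240328)


def representative_model(family: str) -> sc.ParametricSurvival:
    """One plausible parameter set per family (months time scale)."""
    params = {
        "exponential": {"rate": 0.02},
        "weibull": {"shape": 1.3, "scale": 80.0},
        "gamma": {"shape": 1.8, "rate": 0.02},
        "gengamma": {"mu": 4.36038, "sigma": 1.26750, "Q": -3.13596},
        "lognormal": {"meanlog": 4.83614, "sdlog": 1.01581},
        "loglogistic": {"shape": 1.63351, "scale": 112.73457},
        "gompertz": {"shape": 0.02, "rate": 0.005},
    }[family]
    return sc.ParametricSurvival(family, params)
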