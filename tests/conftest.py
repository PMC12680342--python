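"""Shared fixtures: small calibration problems built once per session."""

import pytest

from mcid.estimation import EstimationProblem
from mcid.fixtures import default_designs, glv2, glv3
from mcid.synthetic_data import NoiseModel, generate_dataset


@pytest.fixture(scope="session")
def glv2_fixture():
    return glv2()


@pytest.fixture(scope="session")
def glv3_fixture():
    return glv3()


@pytest.fixture(scope="session")
def glv2_noisefree_problem(glv2_fixture):
    """GLV2, fully observed, two experiments, zero noise."""
    designs = default_designs(glv2_fixture)
    ds = generate_dataset(glv2_fixture["model"], glv2_fixture["theta_nominal"],
                          designs, NoiseModel("proportional", 0.0), seed=11)
    return EstimationProblem(glv2_fixture["model"], designs, ds)


@pytest.fixture(scope="session")
def glv2_noisy_problem(glv2_fixture):
    """GLV2, fully observed, two experiments, 5% proportional noise."""
    designs = default_designs(glv2_fixture)
    ds = generate_dataset(glv2_fixture["model"], glv2_fixture["theta_nominal"],
                          designs, NoiseModel("proportional", 0.05), seed=13)
    return EstimationProblem(glv2_fixture["model"], designs, ds)


@pytest.fixture(scope="session")
def glv3_noisy_problem(glv3_fixture):
    """GLV3, fully observed, both experiments, 10% proportional noise."""
    designs = default_designs(glv3_fixture)
    ds = generate_dataset(glv3_fixture["model"], glv3_fixture["theta_nominal"],
                          designs, NoiseModel("proportional", 0.10), seed=17)
    return EstimationProblem(glv3_fixture["model"], designs, ds)
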