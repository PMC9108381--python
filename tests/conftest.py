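import pytest

from ichecon.costing import TariffTable
from ichecon.qaly import UtilityMap
from ichecon.synthetic_cohort import CohortGenParams, generate_cohort, literature_arm


@pytest.fixture(scope="session")
def tariff():
    return TariffTable.default()


@pytest.fixture(scope="session")
def linear_map():
    return UtilityMap.linear()


@pytest.fixture(scope="session")
def default_cohort():
    """137-patient synthetic cohort at the default (registry-calibrated) params."""
    return generate_cohort(CohortGenParams.default())


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for CI-based marginal checks."""
    params = CohortGenParams.default()
    params.n = 5000
    params.seed = 12345
    return generate_cohort(params)


@pytest.fixture(scope="session")
def arms():
    return {
        name: literature_arm(name)
        for name in (
            "mistie3_intervention",
            "kellner_intervention",
            "catheter_control",
            "endoscopic_control",
        )
    }
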