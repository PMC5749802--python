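import matplotlib
import pytest

matplotlib.use("Agg")

from planktivore import SyntheticScenario
from planktivore.species import DEFAULT_SPECIES, PreyEnergyTable, Species


@pytest.fixture(scope="session")
def prey_ed() -> PreyEnergyTable:
    return PreyEnergyTable()


@pytest.fixture(scope="session")
def herring_params():
    return DEFAULT_SPECIES[Species.HERRING]


@pytest.fixture(scope="session")
def mackerel_params():
    return DEFAULT_SPECIES[Species.MACKEREL]


@pytest.fixture(scope="session")
def blue_whiting_params():
    return DEFAULT_SPECIES[Species.BLUE_WHITING]


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """Single-year, all-species scenario used by the heavier integration tests."""
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def small_results(small_scenario):
    """Fitted results on the small scenario, shared across tests (read-only)."""
    from planktivore import ConsumptionModel

    return ConsumptionModel.from_scenario(small_scenario).fit()
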