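import warnings

import pytest

from trackways.fixtures import engare_sero_fixture
from trackways.synthetic import (
    ExperimentGenConfig,
    PopulationGenConfig,
    generate_anthropometric_population,
    generate_experimental_dataset,
)

# mixed-model boundary warnings are expected with a small subject variance
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def experiment():
    """Default synthetic experimental dataset (seed 0), exclusions applied."""
    gen = generate_experimental_dataset(ExperimentGenConfig(seed=0))
    trials = gen.trials[~gen.trials["excluded"]].reset_index(drop=True)
    return gen, trials


@pytest.fixture(scope="session")
def population():
    """Default synthetic comparative population (seed 1) with its truth."""
    return generate_anthropometric_population(PopulationGenConfig(seed=1))


@pytest.fixture(scope="session")
def engare_sero():
    """Bundled assemblage: (trackways, summaries, stature table)."""
    return engare_sero_fixture()
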