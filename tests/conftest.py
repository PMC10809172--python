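import warnings

import numpy as np
import pytest

from dietewas.config import CohortSpec, SimulationConfig
from dietewas import synthetic

# constant-component and small-panel warnings are expected in fixtures
warnings.filterwarnings("ignore", message="constant component")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Three small cohorts, 250 CpGs, 9 planted diet CpGs (3 mediated)."""
    return SimulationConfig(
        seed=1234,
        cohorts=[
            CohortSpec("alpha", 350, "450K", n_batches=3, female_fraction=1.0,
                       multi_ethnic=True),
            CohortSpec("beta", 300, "450K", n_batches=2, clustered=True),
            CohortSpec("gamma", 250, "EPIC", n_batches=2),
        ],
        n_cpgs=250,
        n_diet_cpgs=9,
        frac_mediated=1 / 3,
        n_smoking_cpgs=12,
        n_bmi_cpgs=12,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthetic.simulate_study(small_config)


@pytest.fixture(scope="session")
def one_cohort():
    """A single mid-sized cohort phenotype table (both sexes)."""
    cfg = SimulationConfig(seed=77, cohorts=[CohortSpec("solo", 400)],
                           n_cpgs=50, n_diet_cpgs=0)
    return synthetic.simulate_cohort(cfg, "solo")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
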