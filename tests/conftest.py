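import logging

import numpy as np
import pandas as pd
import pytest

from zgcalcium import (
    PerfusionProtocol,
    SimConfig,
    simulate_spike_trains,
)

logging.getLogger("zgcalcium").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_protocol():
    return PerfusionProtocol(
        pd.DataFrame(
            {
                "start_s": [0.0, 100.0],
                "end_s": [100.0, 200.0],
                "potassium_mM": [3.0, 3.0],
                "atii_pM": [20.0, 1000.0],
            }
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort (4 animals/genotype x 5 cells) with truth."""
    config = SimConfig(
        n_animals_per_genotype=4,
        slices_per_animal=1,
        cells_per_slice=5,
        seed=42,
    )
    trains, truth = simulate_spike_trains(config)
    return config, trains, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
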