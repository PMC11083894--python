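import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from mitoquant import AnalysisConfig, SimCellParams, simulate_cell

# one constant analysis configuration for the simulated study conditions
SIM_THRESHOLD = 60.0


@pytest.fixture(scope="session")
def sim_config() -> AnalysisConfig:
    return AnalysisConfig(
        threshold_value=SIM_THRESHOLD,
        threshold_nucleus=250.0,
        threshold_cell=150.0,
    )


@pytest.fixture(scope="session")
def simulated_cell():
    """One default-preset three-channel cell with ground truth (seed 0)."""
    return simulate_cell(SimCellParams(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
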