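import numpy as np
import pytest

from dielcycle.config import SimConfig

GRID = np.arange(0.0, 27.0, 2.0)  # 14 samples every 2 h over 26 h


@pytest.fixture
def times():
    return GRID.copy()


@pytest.fixture
def small_config():
    return SimConfig(n_genes=20, seed=0)


@pytest.fixture
def noise_free_config():
    """All noise parameters at zero: the generator becomes deterministic in value."""
    return SimConfig(
        n_genes=12, seed=0, innovation_sd=0.0, peak_sigma=0.0,
        cv_model={"sigma_spread": 0.0}, mixing_bias=[0.0] * len(GRID),
        mixing_bias_sd=0.0, outlier_peak_rate=0.0, outlier_timepoint_rate=0.0,
        fraction_cyclers=0.5,
    )
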