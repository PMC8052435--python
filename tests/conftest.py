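import numpy as np
import pytest

from anchorsmith.io_core import PipelineConfig
from anchorsmith import synthetic_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_config():
    """Pipeline thresholds scaled to the 30x / 10-taxon simulation regime
    (depth gate and per-site occupancy; every matching threshold is the
    protocol default)."""
    return PipelineConfig(min_avg_depth=10, min_sequences_per_site=5)


@pytest.fixture(scope="session")
def tiny_panel():
    """Small shared panel: 4 taxa, 5 loci, 10% divergence."""
    return synthetic_data.simulate_panel(n_taxa=4, n_loci=5, seed=11)
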