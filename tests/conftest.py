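import numpy as np
import pytest

from convvae.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, fast dataset for model unit tests: 120 cells, 2 x 96 bins."""
    cfg = SimConfig(n_cells=120, n_bins=96, n_clusters=3, n_batches=2,
                    peaks_per_cluster=6, library_log_mean=float(np.log(200.0)),
                    batch_effect_sd=0.1, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The standard synthetic benchmark: 600 cells, 2 x 512 bins, 4 clusters."""
    cfg = SimConfig(batch_effect_sd=0.0, seed=1)
    return simulate_dataset(cfg)
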