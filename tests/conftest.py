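import numpy as np
import pytest

from annogcd import SynthConfig, make_split, reduce_pca, simulate_cells
from annogcd.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate, well-separated synthetic dataset shared across fast tests."""
    cfg = SynthConfig(n_types=8, n_cells=800, n_genes=60, separation=8.0,
                      gini_target=0.5, seed=11)
    return simulate_cells(cfg)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    ds = reduce_pca(small_dataset, 32)
    return make_split(ds, known_frac=0.5, labeled_frac=0.7, seed=11)


@pytest.fixture(scope="session")
def fast_cfg():
    """Pipeline config with shortened training for fast functional tests."""
    return PipelineConfig(n_components=32, epochs=150, dgi_epochs=150,
                          min_count=0, seed=11)
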