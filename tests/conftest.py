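import numpy as np
import pandas as pd
import pytest

from expresso.core import ExpressionMap
from expresso.simulate import SimulationConfig, simulate_species_pair


@pytest.fixture
def tiny_maps():
    """Two small maps with replicate-suffixed sample IDs."""
    rng = np.random.default_rng(0)
    genes_a = [f"a{i}" for i in range(1, 7)]
    genes_b = [f"b{i}" for i in range(1, 7)]
    cols_a = ["x.1", "x.2", "y.1", "y.2"]
    cols_b = ["u.1", "u.2", "v.1", "v.2", "w.1", "w.2"]
    map_a = ExpressionMap(
        "A", pd.DataFrame(rng.integers(0, 50, (6, 4)), index=genes_a, columns=cols_a)
    )
    map_b = ExpressionMap(
        "B", pd.DataFrame(rng.integers(0, 50, (6, 6)), index=genes_b, columns=cols_b)
    )
    return map_a, map_b


@pytest.fixture(scope="session")
def small_sim():
    """A fast planted simulation reused by classifier-level tests."""
    config = SimulationConfig(
        n_genes_a=400,
        n_genes_b=400,
        n_sample_labels_a=12,
        n_sample_labels_b=9,
        seed=42,
    )
    return simulate_species_pair(config)
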