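import numpy as np
import pandas as pd
import pytest

from raretide.synthdata import GeneratorConfig, generate
from raretide.tables import AbundanceTable


def make_table(arr, feature_ids=None, sample_ids=None, **kw) -> AbundanceTable:
    arr = np.asarray(arr)
    feature_ids = feature_ids or [f"f{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return AbundanceTable(
        pd.DataFrame(arr, index=feature_ids, columns=sample_ids), **kw
    )


def random_table(rng, n_features=12, n_samples=8, max_count=30, sparsity=0.5,
                 min_col_total=0):
    arr = rng.integers(0, max_count, size=(n_features, n_samples))
    arr[rng.random(arr.shape) < sparsity] = 0
    # keep every sample nonempty; optionally top up to a minimum library size
    for j in range(n_samples):
        if arr[:, j].sum() == 0:
            arr[rng.integers(0, n_features), j] = 1
        deficit = min_col_total - arr[:, j].sum()
        if deficit > 0:
            arr[rng.integers(0, n_features), j] += deficit
    return make_table(arr)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic dataset shared across read-only tests."""
    return generate(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def recovery_config():
    """Conditions for CAG-recovery runs: 8 observable anchors, amplitude 1."""
    return dict(
        n_samples=40,
        n_otus=8,
        n_cags=8,
        genes_per_cag=(30, 30),
        n_background_genes=0,
        rare_fraction=0.0,
        seasonal_amplitude=1.0,
        abundant_amplitude_factor=1.0,
    )
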