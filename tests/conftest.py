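import numpy as np
import pytest

import cellalign as ca


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_counts():
    """Hand-built 6-cell, 4-gene, 2-condition counts dataset."""
    values = np.array([
        [1, 1, 2, 0],
        [4, 0, 4, 2],
        [0, 3, 1, 1],
        [2, 2, 2, 2],
        [5, 1, 0, 4],
        [1, 0, 1, 3],
    ], dtype=float)
    return ca.ExpressionDataset(
        values=values,
        cell_ids=[f"c{i}" for i in range(6)],
        feature_ids=["gA", "gB", "gC", "gD"],
        condition_of=np.array(["s", "s", "s", "t", "t", "t"], dtype=object),
        type_of=np.array(["x", "y", "x", "y", "x", "y"], dtype=object),
        layer="counts",
    )


@pytest.fixture(scope="session")
def small_synth():
    """Fast synthetic instance shared by unit tests (not the acceptance one)."""
    spec = ca.SyntheticSpec(
        n_types=3, cells_per_type_per_condition=40, n_conditions=2,
        n_genes=80, n_markers_per_type=6, marker_effect=2.5,
        condition_effect_global=1.0, seed=7,
    )
    return ca.simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_model(small_synth):
    """A briefly trained alignment model on the small instance."""
    ds, _ = small_synth
    proc, basis = ca.standard_pipeline(ds, pca_dims=16, seed=0)
    cfg = ca.EncoderConfig(hidden_sizes=(32,), embedding_dim=8, max_steps=300,
                           learning_rate=2e-3, dropout_rate=0.0, batch_size=60,
                           perplexity=15, seed=0)
    model = ca.train_alignment(proc, None, cfg)
    return model, proc, basis
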