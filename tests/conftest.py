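import numpy as np
import pytest

from tspminimax import ExpressionDataset, MinimaxConfig


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, labels [0, 0, 1, 1]."""
    return ExpressionDataset(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 9.0, 8.0],
                [5.0, 6.0, 2.0, 1.0],
                [3.0, 3.5, 3.1, 2.9],
            ]
        ),
        labels=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def default_config():
    return MinimaxConfig()


def random_dataset(rng, n_genes=15, n_samples=12):
    """Continuous random dataset with both classes present."""
    labels = np.zeros(n_samples, dtype=int)
    labels[n_samples // 2 :] = 1
    return ExpressionDataset(
        gene_ids=[f"g{i:03d}" for i in range(n_genes)],
        sample_ids=[f"s{j:03d}" for j in range(n_samples)],
        values=rng.normal(size=(n_genes, n_samples)),
        labels=labels,
    )
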