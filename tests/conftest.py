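import numpy as np
import pytest

from coexnet import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples with simple integer values."""
    return ExpressionMatrix(
        gene_ids=("GA", "GB", "GC"),
        sample_ids=("S1", "S2", "S3", "S4"),
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],
                [4.0, 3.0, 2.0, 1.0],
            ]
        ),
    )


def random_expression(rng, n_genes=10, n_samples=30):
    return ExpressionMatrix(
        gene_ids=tuple(f"G{i}" for i in range(n_genes)),
        sample_ids=tuple(f"S{j}" for j in range(n_samples)),
        values=rng.standard_normal((n_genes, n_samples)),
    )
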