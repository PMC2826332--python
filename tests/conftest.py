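import numpy as np
import pytest

from mimosa import ExpressionMatrix, PairData, TripletSpec, generate_triplet, normalize_rows


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


@pytest.fixture
def make_pair():
    """Factory: normalized PairData drawn from the generative triplet model."""

    def factory(f: float, alpha: float, n_samples: int, seed: int) -> PairData:
        trip = generate_triplet(
            TripletSpec(f=f, alpha=alpha, n_samples=n_samples, seed=seed)
        )
        ids = [f"s{i}" for i in range(n_samples)]
        return PairData(_zscore(trip.tf_expr), _zscore(trip.gene_expr), ids)

    return factory


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, unnormalized."""
    return ExpressionMatrix(
        ["TF1", "G1", "G2"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, 1.5, 0.5, 1.5]]),
    )


@pytest.fixture
def normalized_matrix(small_matrix):
    return normalize_rows(small_matrix)
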