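import numpy as np
import pytest

from coregsearch.preprocess import ProcessedDataset, center_rows, reduce_samples


def processed_from_matrix(matrix, dataset_id="ds", genes=None, sample_ids=None, r=20):
    """Build a ProcessedDataset directly from a (will-be-centered) matrix."""
    matrix = center_rows(np.asarray(matrix, dtype=float))
    n, m = matrix.shape
    scores, loadings = reduce_samples(matrix, r=r)
    return ProcessedDataset(
        id=dataset_id,
        genes=genes or [f"g{i + 1}" for i in range(n)],
        scores=scores,
        loadings=loadings,
        total_ss=float((scores**2).sum()),
        sample_ids=sample_ids or [f"s{j + 1}" for j in range(m)],
        sample_words=[frozenset()] * m,
    )


def random_processed(n, m, seed, r=20):
    rng = np.random.default_rng(seed)
    return processed_from_matrix(rng.standard_normal((n, m)), dataset_id=f"rnd{seed}", r=r)


def indicator_for(idx, n):
    vec = np.zeros(n, dtype=np.int8)
    vec[list(idx)] = 1
    return vec


@pytest.fixture
def toy_dataset():
    """Three centered genes over three samples; query {g1, g2} scores 50%."""
    return processed_from_matrix([[1, -1, 0], [1, 0, -1], [0, 1, -1]], dataset_id="toy")
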