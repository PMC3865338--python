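import warnings

import numpy as np
import pytest

from psemetrics.data_model import ItemMatrix, ScoringTensor, worked_example


def make_tensor(values, pictures=None, categories=None, scale_id="t", **kw):
    """Build a ScoringTensor without the all-zero-subject warning noise."""
    values = np.asarray(values)
    n, p, c = values.shape
    if pictures is None:
        pictures = tuple(f"P{i + 1}" for i in range(p))
    if categories is None:
        categories = tuple(f"C{i + 1}" for i in range(c))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ScoringTensor(values, pictures, categories, scale_id=scale_id, **kw)


def random_tensor(rng, n=None, p=None, c=None, density=0.5):
    n = n or rng.integers(3, 20)
    p = p or rng.integers(2, 6)
    c = c or rng.integers(2, 6)
    return make_tensor((rng.random((n, p, c)) < density).astype(int))


def make_matrix(scores, mode="category"):
    scores = np.asarray(scores)
    return ItemMatrix(
        mode=mode,
        items=tuple(f"i{j + 1}" for j in range(scores.shape[1])),
        scores=scores,
    )


@pytest.fixture
def demo():
    return worked_example()


@pytest.fixture
def rng():
    return np.random.default_rng(20231105)
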