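import numpy as np
import pytest

from wvmda import AssociationMatrix, SimilarityMatrix, make_worked_example


@pytest.fixture
def worked_example():
    return make_worked_example()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_association(rng, n, m, density=0.3):
    """Random binary association matrix with at least one association."""
    a = (rng.random((n, m)) < density).astype(np.int8)
    if a.sum() == 0:
        a[rng.integers(n), rng.integers(m)] = 1
    return AssociationMatrix(
        [f"m{i}" for i in range(n)], [f"d{j}" for j in range(m)], a
    )


def random_similarity(rng, names, kind="generic"):
    """Random symmetric unit-diagonal similarity matrix in [0, 1]."""
    k = len(names)
    x = rng.random((k, k))
    x = 0.5 * (x + x.T)
    np.fill_diagonal(x, 1.0)
    return SimilarityMatrix(list(names), x, kind=kind)
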