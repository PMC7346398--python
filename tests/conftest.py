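import numpy as np
import pytest

from fcstrength.types import BoldRun


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_run(data, tr=2.4, mask=None, voxel_size=(2.0, 2.0, 2.0)):
    """Wrap a 4D array as a BoldRun with an all-true mask by default."""
    data = np.asarray(data, dtype=np.float64)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(data=data, tr_seconds=tr, voxel_size_mm=voxel_size, mask=mask)


@pytest.fixture
def small_run(rng):
    """A 5x5x3 random run, 60 volumes."""
    return make_run(rng.normal(size=(5, 5, 3, 60)))


def correlated_series(corr, n_time, rng):
    """Series whose *sample* correlation matrix equals ``corr`` exactly.

    Builds zero-mean orthonormal columns and mixes them with the Cholesky
    factor, so empirical correlations match the target to rounding.
    """
    corr = np.asarray(corr, dtype=np.float64)
    k = corr.shape[0]
    if n_time < k + 1:
        raise ValueError("need n_time >= k + 1")
    w = rng.normal(size=(n_time, k))
    w -= w.mean(axis=0)
    q, _ = np.linalg.qr(w)
    q -= q.mean(axis=0)
    # re-orthonormalize after centering
    q, _ = np.linalg.qr(q)
    chol = np.linalg.cholesky(corr)
    return q @ chol.T  # n_time x k
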