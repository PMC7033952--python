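import numpy as np
import pytest

from gflsgl.data import GroupStructure, LongitudinalDataset
from gflsgl.taskgraph import TaskGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dataset(rng, n=40, p=8, k=3, miss=0.15, noise=0.3,
                 theta=None) -> LongitudinalDataset:
    """Small random regression instance with missing responses."""
    X = rng.normal(size=(n, p))
    if theta is None:
        theta = rng.normal(size=(p, k))
    Y = X @ theta + rng.normal(0, noise, size=(n, k))
    mask = (rng.random((n, k)) >= miss).astype(np.int8)
    for t in range(k):
        if mask[:, t].sum() == 0:
            mask[0, t] = 1
    Y = np.where(mask.astype(bool), Y, np.nan)
    return LongitudinalDataset(X, Y, mask)


def random_groups(rng, p, n_groups) -> GroupStructure:
    perm = rng.permutation(p)
    return GroupStructure([np.sort(a) for a in np.array_split(perm, n_groups)])


@pytest.fixture
def small_instance(rng):
    ds = make_dataset(rng)
    groups = random_groups(rng, ds.p, 3)
    tg = TaskGraph(ds.k, sigma=1.0)
    return ds, groups, tg
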