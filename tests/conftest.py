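import numpy as np
import pytest

from omisurv import simulate_dataset
from omisurv.io_formats import CommunityMatrix, CountTable, SurvivalData
from omisurv.simulator import otu_names, random_coalescent_tree


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_dataset():
    """Small aligned (survival, composition, tree) triple."""
    return simulate_dataset(n=40, p=25, seed=5)


@pytest.fixture
def random_count_table(rng):
    def make(n=8, p=12, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        counts = r.integers(0, 50, size=(n, p))
        counts[:, 0] += 1  # keep row totals positive
        return CountTable(counts, [f"s{i}" for i in range(n)], otu_names(p))

    return make


@pytest.fixture
def random_survival(rng):
    def make(n=50, q=2, tie_fraction=0.0, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        X = r.normal(size=(n, q)) if q else None
        eta = X @ r.normal(scale=0.4, size=q) if q else np.zeros(n)
        T = r.exponential(scale=np.exp(-eta))
        C = r.uniform(0, 2.5, size=n)
        time = np.minimum(T, C)
        if tie_fraction:
            time = np.ceil(time / (tie_fraction * 2)) * (tie_fraction * 2)
        return SurvivalData(time, (T <= C).astype(int), X,
                            sample_ids=[f"s{i}" for i in range(n)])

    return make


@pytest.fixture
def small_tree(rng):
    def make(p=10, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return random_coalescent_tree(p, r)

    return make


@pytest.fixture
def composition(rng):
    def make(n=6, p=10, zero_rows=0, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        counts = r.integers(0, 30, size=(n, p)).astype(float)
        counts[:, -1] += 1
        for i in range(zero_rows):
            counts[i, : p // 2] = 0
        Z = counts / counts.sum(axis=1, keepdims=True)
        return CommunityMatrix(Z, [f"s{i}" for i in range(n)], otu_names(p))

    return make
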