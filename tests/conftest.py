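import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import ZotuTable
from ecoassembly.synthetic_community import simulate_tree


@pytest.fixture
def small_tree():
    """The worked three-tip tree: ((A:1,B:1):1,C:2);"""
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        {"s1": [5, 0, 2], "s2": [3, 4, 1]},
        index=pd.Index(["A", "B", "C"], name="#ZOTU_ID"),
        dtype=np.int64,
    )
    return ZotuTable(df)


def random_table(rng, n_taxa=8, n_samples=5, depth=60, zero_fraction=0.4):
    """Small random count table with some structural zeros; no empty
    samples or taxa."""
    while True:
        base = rng.integers(1, 20, size=(n_taxa, n_samples))
        mask = rng.random((n_taxa, n_samples)) > zero_fraction
        counts = (base * mask).astype(np.int64)
        if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
            break
    taxa = [f"ZOTU_{i + 1}" for i in range(n_taxa)]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    return ZotuTable(pd.DataFrame(counts, index=taxa, columns=samples))


def random_tree(rng, n_taxa=8):
    return simulate_tree(n_taxa, seed=int(rng.integers(2**31)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
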