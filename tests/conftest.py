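import numpy as np
import pytest

from bgyield.bipartite_graph import BipartiteGraph, init_node_features
from bgyield.tabular_io import ColumnSpec, FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_table(rng, n, m, missing_frac=0.2, with_groups=False) -> FeatureTable:
    values = rng.normal(size=(n, m + 1))
    mask = rng.random((n, m + 1)) >= missing_frac
    mask[:, -1] = True  # yield observed
    for j in range(m + 1):  # keep every column minimally observed
        need = min(2, n)
        if mask[:, j].sum() < need:
            mask[rng.choice(n, size=need, replace=False), j] = True
    schema = [ColumnSpec(f"x{j}") for j in range(m)] + [ColumnSpec("yield")]
    groups = rng.choice(["a", "b"], size=n) if with_groups else None
    return FeatureTable(values, mask, schema, groups)


def random_graph(rng, n, f) -> BipartiteGraph:
    weights = rng.normal(size=(n, f))
    sup = rng.random((n, f)) > 0.3
    graph = BipartiteGraph(np.where(sup, weights, 0.0), sup,
                           feat_names=[f"f{j}" for j in range(f)])
    return init_node_features(graph)


@pytest.fixture
def small_table(rng):
    return random_table(rng, n=8, m=4)
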