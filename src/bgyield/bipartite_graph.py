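"""Bipartite graph construction from a feature table.

One node per observation (planting sample) and one per column (m features +
yield). The graph is complete bipartite: all n x (m+1) edges exist, and an
edge carries the standardized cell value as its scalar weight — 0 when the
cell is missing or deliberately hidden. Node features are initialized with
0/1 vectors of length m+1: feature node F_j gets the one-hot unit vector at
position j; observation node N_i gets its observed-cell indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tabular_io import FeatureTable

__all__ = ["BipartiteGraph", "build_bipartite_graph", "init_node_features",
           "save_graph", "load_graph", "GraphConstructionError"]


class GraphConstructionError(ValueError):
    pass


@dataclass
class BipartiteGraph:
    """Complete weighted bipartite graph over observations and features.

    edge_weights[i, j] is the weight of the (N_i, F_j) edge; the
    supervision_mask marks edges whose true value is observed, not hidden,
    and therefore usable as a training label.
    """

    edge_weights: np.ndarray            # n x f
    supervision_mask: np.ndarray        # n x f bool
    obs_init: np.ndarray | None = None  # n x f 0/1
    feat_init: np.ndarray | None = None  # f x f 0/1 (one-hot rows)
    feat_names: list[str] = field(default_factory=list)
    has_yield_node: bool = True

    def __post_init__(self):
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        self.supervision_mask = np.asarray(self.supervision_mask, dtype=bool)
        n, f = self.edge_weights.shape
        if n < 1 or f < 1:
            raise GraphConstructionError("graph needs >=1 observation and >=1 feature node")
        if self.supervision_mask.shape != (n, f):
            raise GraphConstructionError("supervision mask shape mismatch")

    @property
    def n_obs(self) -> int:
        return self.edge_weights.shape[0]

    @property
    def n_feat(self) -> int:
        return self.edge_weights.shape[1]

    @property
    def n_edges(self) -> int:
        """Complete bipartite: n x (m+1)."""
        return self.n_obs * self.n_feat


def build_bipartite_graph(table: FeatureTable,
                          hide_yield_for: np.ndarray | set | None = None,
                          *, include_yield: bool = True,
                          init: bool = True) -> BipartiteGraph:
    """Convert a (standardized) FeatureTable into a bipartite graph.

    `hide_yield_for` lists rows whose yield must be invisible to the network
    (test rows): their yield edge weight is forced to 0 and excluded from
    supervision. With `include_yield=False` the yield feature node is dropped
    entirely (trait-only imputation variant).
    """
    table.require_numeric()
    n, m = table.n, table.m
    if n < 1 or m < 1:
        raise GraphConstructionError("empty table")

    ncols = m + 1 if include_yield else m
    mask = table.mask[:, :ncols].copy()
    if include_yield and hide_yield_for is not None:
        hidden = np.zeros(n, dtype=bool)
        hidden[list(hide_yield_for)] = True
        mask[hidden, -1] = False

    weights = np.where(mask, np.nan_to_num(table.values[:, :ncols], nan=0.0), 0.0)
    graph = BipartiteGraph(weights, mask,
                           feat_names=table.column_names[:ncols],
                           has_yield_node=include_yield)
    if init:
        init_node_features(graph)
    return graph


def init_node_features(graph: BipartiteGraph) -> BipartiteGraph:
    """One-hot feature-node and observed-mask observation-node inits.

    F_j -> unit vector with 1 at position j; N_i -> indicator of which of its
    cells are observed (and not hidden), all-ones for a complete row.
    """
    f = graph.n_feat
    graph.feat_init = np.eye(f)
    graph.obs_init = graph.supervision_mask.astype(float)
    return graph


# ---------------------------------------------------------------------------
# edge-list text serialization
# ---------------------------------------------------------------------------

def save_graph(graph: BipartiteGraph, edges_path, init_path) -> None:
    """Edge list (obs_id, feat_id, weight, supervised) + node-init sidecar."""
    n, f = graph.n_obs, graph.n_feat
    ii, jj = np.meshgrid(np.arange(n), np.arange(f), indexing="ij")
    with open(edges_path, "w") as fh:
        fh.write("obs_id\tfeat_id\tweight\tsupervised\n")
        for i, j in zip(ii.ravel(), jj.ravel()):
            fh.write(f"{i}\t{j}\t{graph.edge_weights[i, j]:.12g}\t"
                     f"{int(graph.supervision_mask[i, j])}\n")
    with open(init_path, "w") as fh:
        fh.write(f"# n_obs={n} n_feat={f} has_yield={int(graph.has_yield_node)}\n")
        fh.write("# feat_names=" + ",".join(graph.feat_names) + "\n")
        for row in graph.obs_init:
            fh.write("O\t" + "\t".join(str(int(v)) for v in row) + "\n")
        for row in graph.feat_init:
            fh.write("F\t" + "\t".join(str(int(v)) for v in row) + "\n")


def load_graph(edges_path, init_path) -> BipartiteGraph:
    data = np.loadtxt(edges_path, skiprows=1)
    data = np.atleast_2d(data)
    n = int(data[:, 0].max()) + 1
    f = int(data[:, 1].max()) + 1
    weights = np.zeros((n, f))
    sup = np.zeros((n, f), dtype=bool)
    for i, j, w, s in data:
        weights[int(i), int(j)] = w
        sup[int(i), int(j)] = bool(s)

    obs_rows, feat_rows, feat_names, has_yield = [], [], [], True
    with open(init_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# feat_names="):
                feat_names = line.split("=", 1)[1].split(",")
            elif line.startswith("#"):
                has_yield = "has_yield=1" in line
            elif line.startswith("O\t"):
                obs_rows.append([float(v) for v in line.split("\t")[1:]])
            elif line.startswith("F\t"):
                feat_rows.append([float(v) for v in line.split("\t")[1:]])
    graph = BipartiteGraph(weights, sup, feat_names=feat_names,
                           has_yield_node=has_yield)
    graph.obs_init = np.array(obs_rows)
    graph.feat_init = np.array(feat_rows)
    return graph
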