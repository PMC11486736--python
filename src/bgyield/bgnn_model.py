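"""The bipartite graph neural network.

Each graph update layer performs two steps on the complete bipartite graph:

1. Node update from incident edge embeddings:
       V_i^{l+1} = L_B( Con[ sum_{j in phi_i} L_A( Con[V_j^l, e_ij^l] ), V_i^l ] )
   with ReLU after both affine maps L_A, L_B, the same weights for both node
   types, and (inverted) dropout on the updated node embeddings in training.

2. Edge update by pure concatenation:
       e_ij^{l+1} = Con[ V_i^{l+1}, V_j^{l+1}, e_ij^l ]

Because step 2 never mixes components, the edge embedding at any layer is a
concatenation of endpoint-node embeddings from earlier layers plus the raw
scalar weight e_ij^0. Every per-edge affine map L_A therefore decomposes
exactly into per-node affine maps plus a rank-one term in e^0, broadcast over
the edge grid. The implementation stores L_A blockwise along that structure
and never materializes per-edge concatenations (the memory and FLOP cost
drops from O(edges x edge_dim) to O(nodes x edge_dim)); `materialize_edges`
reconstructs them explicitly for inspection and testing.

The prediction head maps Con[V_i^L, V_j^L] for a queried (observation,
feature) cell through two fully connected layers to a scalar — used both for
missing-trait imputation (j <= m) and yield prediction (j = m+1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autograd import Adam, Tensor
from .bipartite_graph import BipartiteGraph

__all__ = ["LayerParams", "HeadParams", "ModelParams", "GraphState",
           "init_model", "graph_update_layer", "predict_pairs", "forward",
           "prediction_matrix", "save_checkpoint", "load_checkpoint"]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _edge_block_dims(node_dims: list[int], layer: int) -> list[int]:
    """Component dims of e^l = [Vo^l, Vf^l, ..., Vo^1, Vf^1, e0]."""
    dims = []
    for k in range(layer, 0, -1):
        dims += [node_dims[k], node_dims[k]]
    return dims + [1]


@dataclass
class LayerParams:
    """One graph update layer: blockwise L_A plus two-block L_B.

    wa_blocks rows follow the concat order [V_neighbor^l, e^l]; wb splits as
    [message, self]. p is the dropout probability on updated node embeddings.
    """

    wa_blocks: list[Tensor]
    b_a: Tensor
    wb_msg: Tensor
    wb_self: Tensor
    b_b: Tensor
    p: float = 0.1
    aggregate: str = "mean"  # neighbor aggregation: degree-normalized or raw sum

    def full_wa(self) -> np.ndarray:
        return np.vstack([blk.data for blk in self.wa_blocks])

    def full_wb(self) -> np.ndarray:
        return np.vstack([self.wb_msg.data, self.wb_self.data])

    def tensors(self) -> list[Tensor]:
        return [*self.wa_blocks, self.b_a, self.wb_msg, self.wb_self, self.b_b]


@dataclass
class HeadParams:
    """Two fully connected layers on Con[V_obs, V_feat] -> scalar."""

    w1_obs: Tensor
    w1_feat: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.w1_obs, self.w1_feat, self.b1, self.w2, self.b2]


@dataclass
class ModelParams:
    layers: list[LayerParams]
    head: HeadParams
    node_dims: list[int]  # [input f, h1, h2, ...]
    seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for lp in self.layers:
            out += lp.tensors()
        out += self.head.tensors()
        return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(n_feat_nodes: int, *, hidden: int = 64, n_layers: int = 3,
               head_hidden: int = 64, dropout: float = 0.1,
               aggregate: str = "mean", seed: int = 0) -> ModelParams:
    """Seeded Glorot-uniform initialization of all layers and the head."""
    if n_layers < 1:
        raise ValueError("need at least one graph update layer")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    node_dims = [n_feat_nodes] + [hidden] * n_layers

    layers = []
    for l in range(n_layers):
        d_v = node_dims[l]
        block_dims = [d_v] + _edge_block_dims(node_dims, l)
        d_in = sum(block_dims)
        full = _glorot(rng, d_in, hidden)
        splits = np.cumsum(block_dims)[:-1]
        wa_blocks = [Tensor(b.copy(), requires_grad=True)
                     for b in np.split(full, splits, axis=0)]
        wb_full = _glorot(rng, hidden + d_v, node_dims[l + 1])
        layers.append(LayerParams(
            wa_blocks=wa_blocks,
            b_a=Tensor(np.zeros(hidden), requires_grad=True),
            wb_msg=Tensor(wb_full[:hidden].copy(), requires_grad=True),
            wb_self=Tensor(wb_full[hidden:].copy(), requires_grad=True),
            b_b=Tensor(np.zeros(node_dims[l + 1]), requires_grad=True),
            p=dropout,
            aggregate=aggregate,
        ))

    d_l = node_dims[-1]
    w1 = _glorot(rng, 2 * d_l, head_hidden)
    head = HeadParams(
        w1_obs=Tensor(w1[:d_l].copy(), requires_grad=True),
        w1_feat=Tensor(w1[d_l:].copy(), requires_grad=True),
        b1=Tensor(np.zeros(head_hidden), requires_grad=True),
        w2=Tensor(_glorot(rng, head_hidden, 1), requires_grad=True),
        b2=Tensor(np.zeros(1), requires_grad=True),
    )
    config = {"n_feat_nodes": n_feat_nodes, "hidden": hidden,
              "n_layers": n_layers, "head_hidden": head_hidden,
              "dropout": dropout, "aggregate": aggregate, "seed": seed}
    return ModelParams(layers, head, node_dims, seed, config)


# ---------------------------------------------------------------------------
# graph state
# ---------------------------------------------------------------------------

@dataclass
class GraphState:
    """Node-embedding histories plus the raw edge weights.

    obs_hist[k] / feat_hist[k] are the layer-k embeddings (k=0: the 0/1
    initializations). The layer-l edge embedding is, implicitly,
    Con[Vo^l, Vf^l, ..., Vo^1, Vf^1, e0].
    """

    obs_hist: list[Tensor]
    feat_hist: list[Tensor]
    e0: np.ndarray  # n x f raw (standardized) edge weights
    layer: int = 0

    @property
    def n_obs(self) -> int:
        return self.obs_hist[0].shape[0]

    @property
    def n_feat(self) -> int:
        return self.feat_hist[0].shape[0]

    @property
    def node_dim(self) -> int:
        return self.obs_hist[-1].shape[1]

    @property
    def edge_dim(self) -> int:
        """1 + 2 * sum of post-init node dims (pure-concatenation growth)."""
        return 1 + 2 * sum(t.shape[1] for t in self.obs_hist[1:])

    def materialize_edges(self) -> np.ndarray:
        """Explicit n x f x edge_dim edge embeddings (testing/inspection)."""
        n, f = self.e0.shape
        parts = []
        for k in range(self.layer, 0, -1):
            d = self.obs_hist[k].shape[1]
            parts.append(np.broadcast_to(self.obs_hist[k].data[:, None, :], (n, f, d)))
            parts.append(np.broadcast_to(self.feat_hist[k].data[None, :, :], (n, f, d)))
        parts.append(self.e0[:, :, None])
        return np.concatenate(parts, axis=-1)


def initial_state(graph: BipartiteGraph) -> GraphState:
    if graph.obs_init is None or graph.feat_init is None:
        raise ValueError("graph node features not initialized")
    return GraphState([Tensor(graph.obs_init)], [Tensor(graph.feat_init)],
                      np.asarray(graph.edge_weights, dtype=float))


# ---------------------------------------------------------------------------
# forward computation
# ---------------------------------------------------------------------------

def _fused_message(row: Tensor | None, col: Tensor | None, w_e0: Tensor,
                   b_a: Tensor, e0: np.ndarray, axis: int) -> Tensor:
    """sum_over(axis) ReLU( e0*w + b + row_i + col_j ) as one autograd node.

    The (n, f, h) pre-activation grid is the dominant cost of a layer; this
    computes it with in-place accumulation and an analytic backward (one
    mask-multiply plus axis reductions) instead of a chain of broadcast ops.
    """
    n, f = e0.shape
    h = b_a.shape[0]
    pre = e0[:, :, None] * w_e0.data.reshape(1, 1, h)
    pre += b_a.data
    if row is not None:
        pre += row.data[:, None, :]
    if col is not None:
        pre += col.data[None, :, :]
    mask = pre > 0
    np.maximum(pre, 0.0, out=pre)
    out = Tensor(pre.sum(axis=axis))

    parents = [w_e0, b_a] + ([row] if row is not None else []) \
        + ([col] if col is not None else [])
    if not any(p.requires_grad for p in parents):
        return out

    def backward(g):
        gp = mask * (g[:, None, :] if axis == 1 else g[None, :, :])
        grads = [np.einsum("ijh,ij->h", gp, e0).reshape(1, h),
                 gp.sum(axis=(0, 1))]
        if row is not None:
            grads.append(gp.sum(axis=1))
        if col is not None:
            grads.append(gp.sum(axis=0))
        return tuple(grads)

    out.requires_grad = True
    out._parents = tuple(parents)
    out._backward = backward
    return out


def _aggregated_messages(state: GraphState, wa_blocks: list[Tensor],
                         b_a: Tensor) -> tuple[Tensor, Tensor]:
    """Summed ReLU(L_A(Con[V_neighbor^l, e^l])) for both update directions.

    L_A is applied blockwise along the concatenation structure: the neighbor
    embedding, then [Vo^k, Vf^k] for k = l..1, then e0. The edge-embedding
    projections depend only on the edge's row (observation history) or
    column (feature history) and are shared between the two directions.
    """
    l = state.layer

    obs_sum: Tensor | None = None   # row-indexed terms
    feat_sum: Tensor | None = None  # column-indexed terms
    edge_layers = [k for k in range(l, 0, -1) for _ in (0, 1)]
    edge_sides = ["obs", "feat"] * l
    for blk, side, k in zip(wa_blocks[1:-1], edge_sides, edge_layers):
        emb = state.obs_hist[k] if side == "obs" else state.feat_hist[k]
        term = emb @ blk
        if side == "obs":
            obs_sum = term if obs_sum is None else obs_sum + term
        else:
            feat_sum = term if feat_sum is None else feat_sum + term

    nb_feat = state.feat_hist[l] @ wa_blocks[0]   # neighbor term, obs update
    nb_obs = state.obs_hist[l] @ wa_blocks[0]     # neighbor term, feat update
    col_obs = feat_sum + nb_feat if feat_sum is not None else nb_feat
    row_feat = obs_sum + nb_obs if obs_sum is not None else nb_obs

    msg_obs = _fused_message(obs_sum, col_obs, wa_blocks[-1], b_a,
                             state.e0, axis=1)
    msg_feat = _fused_message(row_feat, feat_sum, wa_blocks[-1], b_a,
                              state.e0, axis=0)
    return msg_obs, msg_feat


def _dropout(t: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    keep = (rng.random(t.shape) >= p).astype(float) / (1.0 - p)
    return t * Tensor(keep)


def graph_update_layer(state: GraphState, params: LayerParams,
                       training: bool = False,
                       rng: np.random.Generator | None = None) -> GraphState:
    """One round of message passing; returns the next GraphState."""
    expected = state.node_dim + state.edge_dim
    got = sum(blk.shape[0] for blk in params.wa_blocks)
    if expected != got:
        raise ValueError(f"L_A input dim mismatch: state gives {expected}, "
                         f"params expect {got}")
    if training and rng is None:
        raise ValueError("training mode needs an rng for dropout")

    # node update: aggregate ReLU(L_A(.)) over the opposite node set
    n, f = state.e0.shape
    msg_obs, msg_feat = _aggregated_messages(state, params.wa_blocks,
                                             params.b_a)
    if params.aggregate == "mean":                # degree-normalized sum
        msg_obs = msg_obs * (1.0 / f)
        msg_feat = msg_feat * (1.0 / n)
    elif params.aggregate != "sum":
        raise ValueError("aggregate must be 'mean' or 'sum'")

    new_obs = (msg_obs @ params.wb_msg
               + state.obs_hist[-1] @ params.wb_self + params.b_b).relu()
    new_feat = (msg_feat @ params.wb_msg
                + state.feat_hist[-1] @ params.wb_self + params.b_b).relu()
    if training and params.p > 0:
        new_obs = _dropout(new_obs, params.p, rng)
        new_feat = _dropout(new_feat, params.p, rng)

    return GraphState(state.obs_hist + [new_obs], state.feat_hist + [new_feat],
                      state.e0, state.layer + 1)


def _fused_head(row: Tensor, col: Tensor, b1: Tensor, w2: Tensor,
                b2: Tensor) -> Tensor:
    """ReLU(row_i + col_j + b1) @ w2 + b2 over the cell grid, one node."""
    n, f = row.shape[0], col.shape[0]
    hh = b1.shape[0]
    pre = row.data[:, None, :] + col.data[None, :, :]
    pre += b1.data
    mask = pre > 0
    np.maximum(pre, 0.0, out=pre)
    out = Tensor(pre.reshape(n * f, hh) @ w2.data + b2.data)
    out = Tensor(out.data.reshape(n, f))

    parents = (row, col, b1, w2, b2)
    if not any(p.requires_grad for p in parents):
        return out

    def backward(g):
        gpre = mask * (g[:, :, None] * w2.data.reshape(1, 1, hh))
        return (gpre.sum(axis=1), gpre.sum(axis=0), gpre.sum(axis=(0, 1)),
                np.einsum("ijh,ij->h", pre, g).reshape(hh, 1),
                np.array([g.sum()]))

    out.requires_grad = True
    out._parents = parents
    out._backward = backward
    return out


def prediction_matrix(state: GraphState, head: HeadParams) -> Tensor:
    """Head output for every (observation, feature) cell: (n, f) tensor."""
    return _fused_head(state.obs_hist[-1] @ head.w1_obs,
                       state.feat_hist[-1] @ head.w1_feat,
                       head.b1, head.w2, head.b2)


def predict_pairs(state: GraphState, pairs, head: HeadParams) -> np.ndarray:
    """Head predictions for the listed (obs i, feat j) cells."""
    n, f = state.e0.shape
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size and (pairs[:, 0].min() < 0 or pairs[:, 0].max() >= n
                       or pairs[:, 1].min() < 0 or pairs[:, 1].max() >= f):
        raise IndexError("pair index out of range")
    full = prediction_matrix(state, head)
    return full.data[pairs[:, 0], pairs[:, 1]].copy()


def run_layers(graph: BipartiteGraph, params: ModelParams,
               training: bool = False,
               rng: np.random.Generator | None = None,
               edge_weights: np.ndarray | None = None,
               obs_init: np.ndarray | None = None) -> GraphState:
    """All graph update layers; optional per-epoch edge/init overrides.

    Overrides let the trainer re-hide cells for an epoch: the hidden cells'
    edge weights drop to 0 and the observation-node indicator vectors mark
    them missing, exactly as a genuinely missing cell looks.
    """
    state = initial_state(graph)
    if edge_weights is not None:
        state.e0 = np.asarray(edge_weights, dtype=float)
    if obs_init is not None:
        state.obs_hist[0] = Tensor(np.asarray(obs_init, dtype=float))
    for lp in params.layers:
        state = graph_update_layer(state, lp, training, rng)
    return state


def forward(graph: BipartiteGraph, params: ModelParams,
            training: bool = False,
            rng: np.random.Generator | None = None
            ) -> tuple[np.ndarray, np.ndarray, GraphState]:
    """Full pass: (imputed standardized table, yield predictions, state).

    The imputed table equals the input on observed (supervised) cells and the
    head's prediction elsewhere; the yield vector is the head's prediction
    for every observation's yield cell.
    """
    state = run_layers(graph, params, training, rng)
    pred = prediction_matrix(state, params.head).data
    imputed = np.where(graph.supervision_mask, graph.edge_weights, pred)
    yield_pred = pred[:, -1].copy() if graph.has_yield_node else np.array([])
    return imputed, yield_pred, state


def decode_categorical(values: np.ndarray, n_labels: int) -> np.ndarray:
    """Round standardized-and-inverted predictions to valid labels 1..n."""
    return np.clip(np.round(values), 1, max(n_labels, 1))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(params: ModelParams, path) -> None:
    """Single .npz archive: all weights + a JSON config snapshot."""
    arrays: dict[str, np.ndarray] = {}
    for li, lp in enumerate(params.layers):
        for bi, blk in enumerate(lp.wa_blocks):
            arrays[f"layer{li}_wa{bi}"] = blk.data
        arrays[f"layer{li}_ba"] = lp.b_a.data
        arrays[f"layer{li}_wbmsg"] = lp.wb_msg.data
        arrays[f"layer{li}_wbself"] = lp.wb_self.data
        arrays[f"layer{li}_bb"] = lp.b_b.data
    for name, t in zip(("w1_obs", "w1_feat", "b1", "w2", "b2"),
                       params.head.tensors()):
        arrays[f"head_{name}"] = t.data
    cfg = dict(params.config)
    cfg["_wa_counts"] = [len(lp.wa_blocks) for lp in params.layers]
    arrays["config_json"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelParams:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["config_json"]).decode())
        params = init_model(cfg["n_feat_nodes"], hidden=cfg["hidden"],
                            n_layers=cfg["n_layers"],
                            head_hidden=cfg["head_hidden"],
                            dropout=cfg["dropout"],
                            aggregate=cfg.get("aggregate", "mean"),
                            seed=cfg["seed"])
        for li, lp in enumerate(params.layers):
            for bi in range(len(lp.wa_blocks)):
                lp.wa_blocks[bi].data = data[f"layer{li}_wa{bi}"].copy()
            lp.b_a.data = data[f"layer{li}_ba"].copy()
            lp.wb_msg.data = data[f"layer{li}_wbmsg"].copy()
            lp.wb_self.data = data[f"layer{li}_wbself"].copy()
            lp.b_b.data = data[f"layer{li}_bb"].copy()
        for name, t in zip(("w1_obs", "w1_feat", "b1", "w2", "b2"),
                           params.head.tensors()):
            t.data = data[f"head_{name}"].copy()
    return params


def make_optimizer(params: ModelParams, lr: float = 1e-3) -> Adam:
    return Adam(params.tensors(), lr=lr)
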