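"""Independent loop-based oracles, kept free of the package's vectorized code.

The forward oracle materializes every concatenation literally and walks the
graph node by node; the metric oracles are plain Python loops. They exist so
the decomposed, vectorized implementations are checked against a second,
structurally different derivation of the same definitions.
"""

import math

import numpy as np


def oracle_forward(graph, params) -> np.ndarray:
    """Literal update rule: per-node loops, explicit concatenated edge vectors."""
    n, f = graph.edge_weights.shape
    Vo = [graph.obs_init[i].astype(float) for i in range(n)]
    Vf = [graph.feat_init[j].astype(float) for j in range(f)]
    E = [[np.array([graph.edge_weights[i, j]]) for j in range(f)] for i in range(n)]

    for lp in params.layers:
        WA, ba = lp.full_wa(), lp.b_a.data
        WB, bb = lp.full_wb(), lp.b_b.data
        new_Vo, new_Vf = [], []
        for i in range(n):
            agg = sum(np.maximum(WA.T @ np.concatenate([Vf[j], E[i][j]]) + ba, 0)
                      for j in range(f))
            if lp.aggregate == "mean":
                agg = agg / f
            new_Vo.append(np.maximum(WB.T @ np.concatenate([agg, Vo[i]]) + bb, 0))
        for j in range(f):
            agg = sum(np.maximum(WA.T @ np.concatenate([Vo[i], E[i][j]]) + ba, 0)
                      for i in range(n))
            if lp.aggregate == "mean":
                agg = agg / n
            new_Vf.append(np.maximum(WB.T @ np.concatenate([agg, Vf[j]]) + bb, 0))
        E = [[np.concatenate([new_Vo[i], new_Vf[j], E[i][j]]) for j in range(f)]
             for i in range(n)]
        Vo, Vf = new_Vo, new_Vf

    head = params.head
    W1 = np.vstack([head.w1_obs.data, head.w1_feat.data])
    out = np.zeros((n, f))
    for i in range(n):
        for j in range(f):
            hid = np.maximum(W1.T @ np.concatenate([Vo[i], Vf[j]]) + head.b1.data, 0)
            out[i, j] = float((head.w2.data.T @ hid + head.b2.data)[0])
    return out


def oracle_metrics(pred, true):
    """(MAE, RMSE, R2) by plain accumulation loops."""
    n = len(true)
    abs_sum = sq_sum = 0.0
    for p, t in zip(pred, true):
        abs_sum += abs(p - t)
        sq_sum += (p - t) ** 2
    ybar = sum(true) / n
    sst = sum((ybar - t) ** 2 for t in true)
    return abs_sum / n, math.sqrt(sq_sum / n), 1.0 - sq_sum / sst


def oracle_ghm(pred, true, alpha):
    total = 0.0
    for p, t in zip(pred, true):
        d = p - t
        total += abs(d) + d / math.sqrt(d * d + alpha * alpha)
    return total / len(true)
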