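"""Training loop, split rule, imputation benchmark and ablation grid.

Splits follow the missing-feature-count rule: rows with at most one missing
feature train the model, rows with two or more are held out, and their yield
edge is zeroed and excluded from supervision before any message passing so
the evaluation cannot leak labels.

The training signal has two parts: the configured loss on the supervised
yield edges of training rows, plus (weight lambda) the same loss on a random
fraction of observed feature cells that are re-hidden each epoch — the
self-supervised imputation signal. Optimization is full-graph Adam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from . import bgnn_model as bm
from .bipartite_graph import BipartiteGraph, build_bipartite_graph
from .losses_metrics import LossConfig, MetricsRecord, compute_metrics, make_loss
from .tabular_io import (FeatureTable, NormParams, apply_normalize,
                         inverse_values, zscore_normalize)

__all__ = ["TrainConfig", "TrainResult", "ExperimentResult",
           "split_by_missingness", "train", "evaluate", "impute_table",
           "baseline_impute", "imputation_experiment", "ablation"]


@dataclass
class TrainConfig:
    epochs: int = 500              # desk-scale default; 20000 mirrors the full protocol
    learning_rate: float = 3e-3
    lr_decay: str = "none"         # optional "cosine" anneal; flat works best here
    loss: LossConfig = field(default_factory=LossConfig)
    dropout: float = 0.1
    n_layers: int = 3
    hidden: int = 64
    head_hidden: int = 64
    recon_weight: float = 0.3      # lambda on the re-hidden feature-cell loss
    rehide_row_frac: float = 0.5   # fraction of train rows re-hidden per epoch
    rehide_cell_range: tuple[float, float] = (0.3, 0.7)  # per-row trait-hiding rate
    include_yield: bool = True     # False = trait-only imputation variant (no yield node)
    early_stop_patience: int = 250
    early_stop_rel_tol: float = 1e-3
    weight_ema: float = 0.0        # optional Polyak averaging (0 disables)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.recon_weight < 0:
            raise ValueError("recon_weight must be >= 0")


@dataclass
class TrainResult:
    params: bm.ModelParams
    history: list[float]
    norm_params: NormParams
    graph: BipartiteGraph
    table: FeatureTable            # original units, with missingness
    train_rows: np.ndarray
    test_rows: np.ndarray
    config: TrainConfig


@dataclass
class ExperimentResult:
    """Per-method x per-rate MAE matrix and/or per-configuration metrics."""

    imputation_mae: pd.DataFrame | None = None
    ablation_table: pd.DataFrame | None = None
    records: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# split rule
# ---------------------------------------------------------------------------

def split_by_missingness(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Rows with <=1 missing feature train; rows with >=2 are held out.

    Missing counts run over the m feature columns only (yield excluded).
    """
    counts = table.feature_missing_counts()
    train = np.flatnonzero(counts <= 1)
    test = np.flatnonzero(counts >= 2)
    if train.size == 0:
        warnings.warn("empty training partition: every row has >=2 missing features")
    if test.size == 0:
        warnings.warn("empty test partition: no row has >=2 missing features")
    return train, test


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _prepare(table: FeatureTable, config: TrainConfig,
             train_rows: np.ndarray | None, test_rows: np.ndarray | None):
    if train_rows is None or test_rows is None:
        train_rows, test_rows = split_by_missingness(table)
    fit_mask = np.zeros(table.n, dtype=bool)
    fit_mask[train_rows] = True
    if not fit_mask.any():      # degenerate but legal for trait-only runs
        fit_mask[:] = True
    norm_table, norm_params = zscore_normalize(table, fit_mask)
    graph = build_bipartite_graph(norm_table, hide_yield_for=test_rows,
                                  include_yield=config.include_yield)
    return graph, norm_params, np.asarray(train_rows), np.asarray(test_rows)


def train(table: FeatureTable, config: TrainConfig | None = None,
          train_rows: np.ndarray | None = None,
          test_rows: np.ndarray | None = None) -> TrainResult:
    """Fit the bipartite network on one table; seeded and reproducible."""
    config = config or TrainConfig()
    graph, norm_params, train_rows, test_rows = _prepare(
        table, config, train_rows, test_rows)
    n, f = graph.edge_weights.shape

    if config.include_yield and not graph.supervision_mask[train_rows, -1].any():
        raise ValueError("no supervised yield cell among training rows")

    params = bm.init_model(f, hidden=config.hidden, n_layers=config.n_layers,
                           head_hidden=config.head_hidden,
                           dropout=config.dropout, seed=config.seed)
    optimizer = bm.make_optimizer(params, lr=config.learning_rate)
    loss_fn = make_loss(config.loss)

    drop_rng = np.random.default_rng([config.seed, 101])
    hide_rng = np.random.default_rng([config.seed, 103])

    # self-supervision by row-clustered re-hiding: each epoch a subset of
    # train rows is degraded to look like a sparse row (a large random share
    # of its observed traits hidden, plus its yield edge), and the network is
    # supervised on exactly the hidden cells. It therefore never merely reads
    # a row's own value back off an input edge, and it trains on the
    # many-traits-missing patterns it must impute at evaluation time.
    feat_sup = graph.supervision_mask.copy()
    if config.include_yield:
        feat_sup[:, -1] = False
    # degrade only columns that actually lose values in this table (weather
    # aggregates are always complete; traits are the missingness-prone block)
    ncols = feat_sup.shape[1]
    prone = ~table.mask[:, :ncols].all(axis=0)
    if prone.any():
        feat_sup &= prone[None, :]
    sup_yield_rows = np.array([], dtype=int)
    if config.include_yield:
        sup_yield_rows = train_rows[graph.supervision_mask[train_rows, -1]]
    hide_pool = sup_yield_rows if config.include_yield else train_rows
    n_rows_hide = max(1, int(round(config.rehide_row_frac * hide_pool.size))) \
        if hide_pool.size else 0
    lo, hi = config.rehide_cell_range

    history: list[float] = []
    ema, best, stale = None, np.inf, 0
    # Polyak-averaged weights damp the epoch-to-epoch jitter injected by the
    # stochastic re-hiding; they become the evaluation parameters
    avg = [t.data.copy() for t in params.tensors()] \
        if 0 < config.weight_ema < 1 else None
    for epoch in range(config.epochs):
        # leakage guard: hidden test yields are zero-weight and unsupervised
        if config.include_yield and test_rows.size:
            assert not graph.supervision_mask[test_rows, -1].any()
            assert np.all(graph.edge_weights[test_rows, -1] == 0.0)

        e0 = graph.edge_weights.copy()
        obs_init = graph.obs_init.copy()
        yrows = np.array([], dtype=int)
        hidden = np.array([], dtype=int)
        if n_rows_hide:
            yrows = hide_rng.choice(hide_pool, size=n_rows_hide, replace=False)
            rates = hide_rng.uniform(lo, hi, size=n_rows_hide)
            hide_cells = feat_sup[yrows] & (
                hide_rng.random((n_rows_hide, f)) < rates[:, None])
            hidden = (yrows[:, None] * f
                      + np.arange(f)[None, :])[hide_cells].ravel()
            e0.ravel()[hidden] = 0.0
            obs_init.ravel()[hidden] = 0.0
            if config.include_yield:
                e0[yrows, -1] = 0.0
                obs_init[yrows, -1] = 0.0

        state = bm.run_layers(graph, params, training=True, rng=drop_rng,
                              edge_weights=e0, obs_init=obs_init)
        pred = bm.prediction_matrix(state, params.head)

        terms = []
        if config.include_yield and yrows.size:
            yidx = yrows * f + (f - 1)
            terms.append(loss_fn(pred.reshape(-1).take_flat(yidx),
                                 graph.edge_weights[yrows, -1]))
        if config.recon_weight > 0 and hidden.size:
            recon = loss_fn(pred.reshape(-1).take_flat(hidden),
                            graph.edge_weights.ravel()[hidden])
            terms.append(recon * config.recon_weight)
        if not terms:
            raise ValueError("no training signal: yield excluded and lambda=0")
        total = terms[0]
        for t in terms[1:]:
            total = total + t

        if config.lr_decay == "cosine":
            optimizer.lr = config.learning_rate * (
                0.55 + 0.45 * np.cos(np.pi * epoch / config.epochs))

        value = float(total.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={value}")
        history.append(value)

        optimizer.zero_grad()
        total.backward()
        optimizer.step()
        if avg is not None:
            k = config.weight_ema
            for acc, t in zip(avg, params.tensors()):
                acc *= k
                acc += (1 - k) * t.data

        # plateau detection on a smoothed loss: the raw series is noisy
        # because every epoch re-hides a fresh random cell pattern
        ema = value if ema is None else 0.05 * value + 0.95 * ema
        if ema < best * (1 - config.early_stop_rel_tol):
            best, stale = ema, 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break

    if avg is not None:
        # debias toward the raw weights for short runs
        k = 1.0 - config.weight_ema ** len(history)
        for acc, t in zip(avg, params.tensors()):
            t.data = acc / k if k > 0.1 else t.data
    return TrainResult(params, history, norm_params, graph, table,
                       train_rows, test_rows, config)


# ---------------------------------------------------------------------------
# evaluation and imputation
# ---------------------------------------------------------------------------

def predict_yield(result: TrainResult, rows: np.ndarray | None = None) -> np.ndarray:
    """Yield predictions in original kg/acre units."""
    if not result.config.include_yield:
        raise ValueError("trait-only model has no yield node")
    _, yhat_std, _ = bm.forward(result.graph, result.params, training=False)
    ycol = result.graph.n_feat - 1
    yhat = inverse_values(yhat_std, result.norm_params, ycol)
    return yhat if rows is None else yhat[np.asarray(rows)]


def evaluate(result: TrainResult, rows: np.ndarray | None = None,
             groups: np.ndarray | None = None) -> MetricsRecord:
    """Test-set yield metrics in original units (inverse z-transform applied)."""
    rows = result.test_rows if rows is None else np.asarray(rows)
    observed = result.table.mask[rows, -1]
    rows = rows[observed]
    if rows.size < 2:
        raise ValueError("need >=2 evaluation rows with observed yield")
    yhat = predict_yield(result, rows)
    ytrue = result.table.values[rows, -1]
    if groups is None and result.table.groups is not None:
        groups = result.table.groups[rows]
    return compute_metrics(yhat, ytrue, groups)


def impute_table(result: TrainResult) -> FeatureTable:
    """Fill missing cells with model predictions, in original units.

    Observed cells pass through unchanged; categorical imputations are
    rounded to the nearest valid label.
    """
    imputed_std, _, _ = bm.forward(result.graph, result.params, training=False)
    out = result.table.copy()
    ncols = result.graph.n_feat
    for j in range(ncols):
        missing = ~out.mask[:, j]
        if not missing.any():
            continue
        vals = inverse_values(imputed_std[missing, j], result.norm_params, j)
        spec = out.column_schema[j]
        if spec.kind == "categorical" and spec.label_map:
            vals = bm.decode_categorical(vals, max(spec.label_map.values()))
        out.values[missing, j] = vals
        out.mask[missing, j] = True
    return out


# ---------------------------------------------------------------------------
# simple imputation baselines
# ---------------------------------------------------------------------------

def baseline_impute(table: FeatureTable, method: str, k: int = 5) -> FeatureTable:
    """mean / median column fills, or k-nearest-rows fill (nan-Euclidean)."""
    table.require_numeric()
    out = table.copy()
    vals = out.values[:, :-1]
    mask = out.mask[:, :-1]
    empty = np.flatnonzero(~mask.any(axis=0))
    if empty.size:
        raise ValueError(
            f"all-missing column: {out.column_schema[empty[0]].name!r}")

    if method in ("mean", "median"):
        fill = (np.nanmean if method == "mean" else np.nanmedian)(vals, axis=0)
        filled = np.where(mask, vals, fill[None, :])
    elif method == "knn":
        mu = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0)
        sd[sd == 0] = 1.0
        filled = KNNImputer(n_neighbors=k).fit_transform((vals - mu) / sd)
        filled = filled * sd + mu
    else:
        raise ValueError(f"unknown baseline method {method!r}")

    out.values[:, :-1] = np.where(mask, vals, filled)
    out.mask[:, :-1] = True
    return out


# ---------------------------------------------------------------------------
# random-deletion imputation benchmark
# ---------------------------------------------------------------------------

def complete_rows(table: FeatureTable) -> FeatureTable:
    """Restrict to rows with no missing cells at all."""
    keep = table.mask.all(axis=1)
    if not keep.any():
        raise ValueError("no complete rows in table")
    return FeatureTable(table.values[keep], table.mask[keep],
                        table.column_schema,
                        None if table.groups is None else table.groups[keep])


def imputation_experiment(table: FeatureTable,
                          rates=(0.1, 0.2, 0.3),
                          methods=("mean", "median", "knn", "bgnn"),
                          seed: int = 0,
                          train_config: TrainConfig | None = None,
                          knn_k: int = 5) -> ExperimentResult:
    """Random-deletion benchmark on complete rows.

    For each rate, feature cells are deleted uniformly at random; each method
    fills them; the score is the MAE between fill and held-out truth on
    deleted cells only, in original units. The network runs as its trait-only
    variant (yield feature node removed).
    """
    from .synthetic_data import apply_missingness  # local: avoids cycle

    for r in rates:
        if not 0 < r < 1:
            raise ValueError(f"rate {r} outside (0, 1)")
    base = complete_rows(table)
    truth = base.values.copy()

    mae = pd.DataFrame(index=list(methods),
                       columns=[f"{r:.0%}" for r in rates], dtype=float)
    for ri, rate in enumerate(rates):
        masked, deleted = apply_missingness(base, rate, "MCAR",
                                            seed=seed * 1000 + ri)
        for method in methods:
            if method == "bgnn":
                cfg = replace(train_config or TrainConfig(),
                              include_yield=False, seed=seed)
                res = train(masked, cfg,
                            train_rows=np.arange(base.n),
                            test_rows=np.array([], dtype=int))
                filled = impute_table(res)
            else:
                filled = baseline_impute(masked, method, k=knn_k)
            err = np.abs(filled.values - truth)[deleted]
            mae.loc[method, f"{rate:.0%}"] = float(err.mean())
    return ExperimentResult(imputation_mae=mae)


# ---------------------------------------------------------------------------
# ablation grid
# ---------------------------------------------------------------------------

def default_ablation_grid() -> list[tuple[str, dict]]:
    """The ten reported rows; overlapping rows share the base configuration."""
    return [
        ("Random inactivation is not used", {"dropout": 0.0}),
        ("Random inactivation is used", {}),
        ("the number of graph update layers is 2", {"n_layers": 2}),
        ("the number of graph update layers is 4", {"n_layers": 4}),
        ("the number of graph update layers is 3", {}),
        ("L1 loss is used", {"loss": LossConfig("L1")}),
        ("L2 loss is used", {"loss": LossConfig("L2")}),
        ("LGHM loss (alpha=0.5) is used", {"loss": LossConfig("GHM", 0.5)}),
        ("LGHM loss (alpha=0.7) is used", {"loss": LossConfig("GHM", 0.7)}),
        ("LGHM loss (alpha=0.3) is used", {}),
    ]


def ablation(table: FeatureTable, grid: list[tuple[str, dict]] | None = None,
             base_config: TrainConfig | None = None) -> ExperimentResult:
    """Train one model per configuration on a shared split and seed.

    Rows whose overrides resolve to the same configuration reuse one run, so
    the default ten-row grid costs eight trainings.
    """
    grid = grid if grid is not None else default_ablation_grid()
    base = base_config or TrainConfig()
    train_rows, test_rows = split_by_missingness(table)

    cache: dict[tuple, tuple[MetricsRecord, TrainResult]] = {}
    rows = []
    for label, overrides in grid:
        cfg = replace(base, **overrides)
        key = (cfg.dropout, cfg.n_layers, cfg.loss.kind, cfg.loss.alpha)
        if key not in cache:
            res = train(table, cfg, train_rows=train_rows, test_rows=test_rows)
            cache[key] = (evaluate(res), res)
        rec = cache[key][0]
        rows.append({"Items": label, "RMSE": rec.rmse, "MAE": rec.mae,
                     "R2": rec.r2})
    out = ExperimentResult(ablation_table=pd.DataFrame(rows))
    out.records = {label: cache[(replace(base, **ov).dropout,
                                 replace(base, **ov).n_layers,
                                 replace(base, **ov).loss.kind,
                                 replace(base, **ov).loss.alpha)][0]
                   for label, ov in grid}
    return out
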