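"""Training losses and evaluation metrics.

The gradient-harmonized loss augments L1 with a bounded term
|d| / sqrt(d^2 + alpha^2), d = prediction - truth, which tempers each
sample's influence by its residual magnitude: samples from thinly sampled
planting locations tend to carry larger residuals, and the extra term
re-weights the gradient they contribute. alpha (default 0.3) sets the
residual scale at which the term saturates; as alpha -> infinity the loss
collapses to plain L1.

The default is the even ("absolute") form. A signed variant, with d rather
than |d| in the numerator, is also provided, but it is degenerate as a
training objective: for under-predictions the two terms cancel and the
per-sample loss vanishes as d -> -infinity, so a network trained on it is
rewarded for predicting arbitrarily low values. Both variants agree for
non-negative residuals.

All loss functions accept either NumPy arrays or autograd Tensors, so the
same definitions drive both training and closed-form checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor

__all__ = ["LossConfig", "MetricsRecord", "ghm_loss", "l1_loss", "l2_loss",
           "make_loss", "compute_metrics"]

_LOSS_KINDS = ("L1", "L2", "GHM")


@dataclass
class LossConfig:
    kind: str = "GHM"
    alpha: float = 0.3
    variant: str = "absolute"  # or "signed" (the printed form; see ghm_loss)

    def __post_init__(self):
        if self.kind not in _LOSS_KINDS:
            raise ValueError(f"loss kind must be one of {_LOSS_KINDS}")
        if self.kind == "GHM" and self.alpha <= 0:
            raise ValueError("GHM alpha must be positive")
        if self.variant not in ("signed", "absolute"):
            raise ValueError("variant must be 'signed' or 'absolute'")

    def label(self) -> str:
        return f"GHM(alpha={self.alpha})" if self.kind == "GHM" else self.kind


def _check_nonempty(pred, true):
    np_pred = pred.data if isinstance(pred, Tensor) else np.asarray(pred, float)
    np_true = true.data if isinstance(true, Tensor) else np.asarray(true, float)
    if np_pred.size == 0 or np_true.size == 0:
        raise ValueError("empty input to loss")
    if np_pred.shape != np_true.shape:
        raise ValueError("pred/true length mismatch")


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def ghm_loss(pred, true, alpha: float = 0.3, variant: str = "absolute"):
    """(1/N) sum_i [ |d_i| + |d_i| / sqrt(d_i^2 + alpha^2) ], d = pred - true.

    variant="signed" uses d_i in the second numerator instead of |d_i|; see
    the module docstring for why that form is unsuitable for optimization.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    _check_nonempty(pred, true)
    symbolic = isinstance(pred, Tensor) or isinstance(true, Tensor)
    d = _wrap(pred) - _wrap(true)
    num = d.abs() if variant == "absolute" else d
    out = (d.abs() + num / (d * d + alpha * alpha).sqrt()).mean()
    return out if symbolic else float(out.data)


def l1_loss(pred, true):
    """Mean absolute residual."""
    _check_nonempty(pred, true)
    symbolic = isinstance(pred, Tensor) or isinstance(true, Tensor)
    out = (_wrap(pred) - _wrap(true)).abs().mean()
    return out if symbolic else float(out.data)


def l2_loss(pred, true):
    """Mean squared residual."""
    _check_nonempty(pred, true)
    symbolic = isinstance(pred, Tensor) or isinstance(true, Tensor)
    d = _wrap(pred) - _wrap(true)
    out = (d * d).mean()
    return out if symbolic else float(out.data)


def make_loss(config: LossConfig):
    """Loss function (pred, true) -> scalar for a LossConfig."""
    if config.kind == "L1":
        return l1_loss
    if config.kind == "L2":
        return l2_loss
    return lambda p, t: ghm_loss(p, t, config.alpha, config.variant)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsRecord:
    mae: float
    rmse: float
    r2: float
    n: int
    per_group: dict[str, "MetricsRecord"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"MAE": self.mae, "RMSE": self.rmse, "R2": self.r2, "n": self.n}
        if self.per_group:
            d["per_group"] = {k: v.to_dict() for k, v in self.per_group.items()}
        return d


def _metrics_1(pred: np.ndarray, true: np.ndarray, require_r2: bool) -> MetricsRecord:
    resid = pred - true
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((true - true.mean()) ** 2))
    if sst == 0:
        if require_r2:
            raise ValueError("R^2 undefined: constant true values")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / sst
    return MetricsRecord(mae, rmse, r2, len(true))


def compute_metrics(pred, true, groups=None) -> MetricsRecord:
    """MAE, RMSE and R^2 = 1 - SS_res/SS_tot, globally and per group.

    Per-group R^2 is reported as NaN when a group's true values are constant
    (its MAE/RMSE remain meaningful); the global R^2 requires variation.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape:
        raise ValueError("pred/true length mismatch")
    if pred.size < 1:
        raise ValueError("empty input")
    rec = _metrics_1(pred, true, require_r2=True)
    if groups is not None:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            sel = groups == g
            rec.per_group[str(g)] = _metrics_1(pred[sel], true[sel], require_r2=False)
    return rec


def metrics_report(record: MetricsRecord, config: dict | None = None) -> str:
    """Structured JSON report: {global, per_group, n, config_hash}."""
    payload = {
        "global": {"MAE": record.mae, "RMSE": record.rmse, "R2": record.r2},
        "per_group": {k: v.to_dict() for k, v in record.per_group.items()},
        "n": record.n,
        "config_hash": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest()[:12],
    }
    return json.dumps(payload, indent=2, allow_nan=True)
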