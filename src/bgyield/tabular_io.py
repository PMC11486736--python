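"""Feature-table I/O, categorical encoding, z-scoring, and weather aggregation.

The central container is :class:`FeatureTable`: an n x (m+1) real matrix whose
last column is the yield (kg/acre semantics), an observed-cell mask, a
per-column schema (continuous vs categorical trait), and per-row planting
location group labels. Missingness lives in the mask; unobserved cells hold
NaN and are never used in arithmetic.

Daily meteorological series (10 dimensions per day over each sample's growth
window) are collapsed to 20 features: the per-dimension mean and population
variance across the window.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSpec", "FeatureTable", "NormParams", "DailySeries",
    "read_table", "write_table", "encode_categoricals",
    "zscore_normalize", "inverse_normalize", "aggregate_daily_weather",
    "read_daily_weather",
    "FormatError", "SchemaError", "EncodingError", "DegenerateColumnError",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class FormatError(ValueError):
    """Malformed input file (ragged rows, empty table...)."""


class SchemaError(ValueError):
    """Column kind or schema inconsistency."""


class EncodingError(ValueError):
    """Unseen category under a frozen label map."""


class DegenerateColumnError(ValueError):
    """Zero-variance or under-observed column during normalization."""


@dataclass
class ColumnSpec:
    name: str
    kind: str = CONTINUOUS
    label_map: dict[str, int] | None = None

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")


@dataclass
class FeatureTable:
    """Observations x (features + yield) with explicit missingness.

    values[i, j] is NaN exactly where mask[i, j] is False. The last column is
    the yield. Text categorical columns read from disk are held aside in
    ``raw_text`` until :func:`encode_categoricals` assigns integer labels.
    """

    values: np.ndarray
    mask: np.ndarray
    column_schema: list[ColumnSpec]
    groups: np.ndarray | None = None
    raw_text: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise SchemaError("values and mask shapes differ")
        n, p = self.values.shape
        if n < 1 or p < 2:
            raise FormatError("table needs at least 1 row and 1 feature + yield")
        if len(self.column_schema) != p:
            raise SchemaError("schema length does not match column count")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != n:
                raise SchemaError("groups length does not match row count")
        # unobserved cells must not carry values
        vals = self.values.copy()
        vals[~self.mask] = np.nan
        self.values = vals

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of feature columns (excluding yield)."""
        return self.values.shape[1] - 1

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.column_schema]

    @property
    def yield_index(self) -> int:
        return self.values.shape[1] - 1

    def feature_missing_counts(self) -> np.ndarray:
        """Per-row count of missing feature cells (yield excluded)."""
        return (~self.mask[:, :-1]).sum(axis=1)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.mask.copy(),
            [replace(c, label_map=None if c.label_map is None else dict(c.label_map))
             for c in self.column_schema],
            None if self.groups is None else self.groups.copy(),
            {k: v.copy() for k, v in self.raw_text.items()},
        )

    def require_numeric(self):
        if self.raw_text:
            cols = [self.column_schema[j].name for j in self.raw_text]
            raise SchemaError(f"text categorical columns not yet encoded: {cols}")


@dataclass
class NormParams:
    """Frozen per-column z-score parameters (fit on observed training cells)."""

    mean: np.ndarray
    std: np.ndarray
    normalized: np.ndarray  # bool flag per column

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=bool)
        if not (len(self.mean) == len(self.std) == len(self.normalized)):
            raise SchemaError("NormParams field lengths differ")
        if np.any(self.std[self.normalized] <= 0):
            raise DegenerateColumnError("non-positive sigma in NormParams")

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "std": self.std.tolist(),
                           "normalized": self.normalized.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "NormParams":
        d = json.loads(text)
        return cls(np.array(d["mean"]), np.array(d["std"]), np.array(d["normalized"]))


@dataclass
class DailySeries:
    """Daily 10-dimensional meteorological readings over one growth window."""

    start_date: str
    end_date: str
    daily: np.ndarray  # days x 10

    def __post_init__(self):
        self.daily = np.atleast_2d(np.asarray(self.daily, dtype=float))
        if self.daily.shape[0] < 1:
            raise FormatError("growth window must cover at least one day")


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_table(path_or_buf, schema: dict[str, str] | None = None, *,
               delimiter: str = ",", na_token: str = "NA",
               yield_column: str | None = None,
               group_column: str | None = None) -> FeatureTable:
    """Read a CSV/TSV feature table.

    `schema` maps column name -> kind ("continuous"/"categorical"); unlisted
    columns default to continuous. The yield column (default: last data
    column) is moved to the last position. `group_column`, if present, becomes
    the per-row group labels rather than a feature.
    """
    na_values = {na_token, ""} if na_token else {""}
    try:
        df = pd.read_csv(path_or_buf, sep=delimiter, dtype=str,
                         keep_default_na=False, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse table: {exc}") from exc
    if df.shape[0] == 0:
        raise FormatError("table has a header but no data rows")
    if any(str(c).startswith("Unnamed") for c in df.columns):
        raise FormatError("ragged rows or missing header fields")

    groups = None
    if group_column is not None and group_column in df.columns:
        groups = df[group_column].to_numpy()
        df = df.drop(columns=[group_column])

    cols = list(df.columns)
    ycol = yield_column if yield_column is not None else cols[-1]
    if ycol not in cols:
        raise SchemaError(f"yield column {ycol!r} not in table")
    cols = [c for c in cols if c != ycol] + [ycol]
    df = df[cols]

    schema = dict(schema or {})
    specs = [ColumnSpec(c, schema.get(c, CONTINUOUS)) for c in cols]

    n, p = df.shape
    values = np.full((n, p), np.nan)
    mask = np.ones((n, p), dtype=bool)
    raw_text: dict[int, np.ndarray] = {}
    for j, c in enumerate(cols):
        col = df[c].to_numpy()
        missing = np.array([str(v).strip() in na_values for v in col])
        mask[:, j] = ~missing
        try:
            num = np.array([float(v) if not miss else np.nan
                            for v, miss in zip(col, missing)])
            values[:, j] = num
        except ValueError:
            if specs[j].kind != CATEGORICAL:
                raise SchemaError(
                    f"non-numeric values in continuous column {c!r}") from None
            raw = col.astype(object)
            raw[missing] = None
            raw_text[j] = raw
    return FeatureTable(values, mask, specs, groups, raw_text)


def write_table(table: FeatureTable, path, *, delimiter: str = ",",
                na_token: str = "NA", float_format: str = "%.10g") -> None:
    """Write a FeatureTable back to CSV/TSV; read_table round-trips it."""
    table.require_numeric()
    df = pd.DataFrame(table.values, columns=table.column_names)
    # categorical labels as integers for readability
    for j, spec in enumerate(table.column_schema):
        if spec.kind == CATEGORICAL:
            col = df.iloc[:, j]
            df.isetitem(j, col.map(lambda v: "" if pd.isna(v) else str(int(v))))
    if table.groups is not None:
        df.insert(0, "group", table.groups)
    df.to_csv(path, sep=delimiter, index=False, na_rep=na_token,
              float_format=float_format)


# ---------------------------------------------------------------------------
# categorical encoding
# ---------------------------------------------------------------------------

def encode_categoricals(table: FeatureTable,
                        label_maps: dict[str, dict[str, int]] | None = None
                        ) -> FeatureTable:
    """Assign positive integer labels (1, 2, ...) to categorical text columns.

    First-appearance order unless an explicit label map is supplied for the
    column; a frozen map raises :class:`EncodingError` on unseen categories.
    Missing cells stay missing.
    """
    out = table.copy()
    label_maps = label_maps or {}
    for j, spec in enumerate(out.column_schema):
        if spec.kind != CATEGORICAL:
            continue
        if j in out.raw_text:
            raw = out.raw_text.pop(j)
            frozen = label_maps.get(spec.name, spec.label_map)
            lmap = dict(frozen) if frozen else {}
            col = np.full(out.n, np.nan)
            for i, v in enumerate(raw):
                if v is None:
                    continue
                key = str(v).strip()
                if key not in lmap:
                    if frozen is not None:
                        raise EncodingError(
                            f"unseen category {key!r} in column {spec.name!r}")
                    lmap[key] = len(lmap) + 1
                col[i] = lmap[key]
            out.values[:, j] = col
            spec.label_map = lmap
        else:
            observed = out.values[out.mask[:, j], j]
            if observed.size and (np.any(observed < 1)
                                  or np.any(observed != np.round(observed))):
                raise EncodingError(
                    f"categorical column {spec.name!r} holds non-positive or "
                    "non-integer labels")
            if spec.label_map is None:
                spec.label_map = {str(int(v)): int(v)
                                  for v in np.unique(observed[~np.isnan(observed)])}
    return out


# ---------------------------------------------------------------------------
# z-score normalization (population sigma)
# ---------------------------------------------------------------------------

def zscore_normalize(table: FeatureTable, fit_mask: np.ndarray | None = None,
                     columns: np.ndarray | None = None
                     ) -> tuple[FeatureTable, NormParams]:
    """Standardize each column: t' = (t - mu) / sigma.

    mu and sigma (population, divide-by-N) are fit only on observed cells of
    the rows selected by `fit_mask` (all rows by default) and frozen; applying
    them to other rows never re-estimates. `columns` (bool per column)
    restricts which columns are transformed.
    """
    table.require_numeric()
    n, p = table.values.shape
    fit_rows = np.ones(n, dtype=bool) if fit_mask is None else np.asarray(fit_mask, bool)
    do = np.ones(p, dtype=bool) if columns is None else np.asarray(columns, bool)

    mean = np.zeros(p)
    std = np.ones(p)
    for j in range(p):
        if not do[j]:
            continue
        cells = table.values[fit_rows & table.mask[:, j], j]
        if cells.size < 2:
            raise DegenerateColumnError(
                f"column {table.column_schema[j].name!r} has <2 observed fit values")
        mu, sigma = cells.mean(), cells.std()  # population sigma
        if sigma == 0:
            raise DegenerateColumnError(
                f"column {table.column_schema[j].name!r} has zero variance")
        mean[j], std[j] = mu, sigma

    params = NormParams(mean, std, do)
    return apply_normalize(table, params), params


def apply_normalize(table: FeatureTable, params: NormParams) -> FeatureTable:
    out = table.copy()
    d = out.mask & params.normalized[None, :]
    out.values[d] = ((out.values - params.mean[None, :]) / params.std[None, :])[d]
    return out


def inverse_normalize(table: FeatureTable, params: NormParams) -> FeatureTable:
    """Undo :func:`zscore_normalize`; round-trips to 1e-12."""
    out = table.copy()
    d = out.mask & params.normalized[None, :]
    out.values[d] = (out.values * params.std[None, :] + params.mean[None, :])[d]
    return out


def inverse_values(x: np.ndarray, params: NormParams, column: int) -> np.ndarray:
    """Map standardized values of one column back to original units."""
    if not params.normalized[column]:
        return np.asarray(x, dtype=float)
    return np.asarray(x, dtype=float) * params.std[column] + params.mean[column]


# ---------------------------------------------------------------------------
# daily weather aggregation
# ---------------------------------------------------------------------------

def aggregate_daily_weather(series: DailySeries) -> np.ndarray:
    """Collapse a days x 10 window to [mean_1..mean_10, var_1..var_10].

    Population variance, so a 1-day window yields zero variances.
    """
    daily = series.daily
    if daily.shape[0] < 1:
        raise FormatError("empty growth window")
    return np.concatenate([daily.mean(axis=0), daily.var(axis=0)])


def read_daily_weather(path_or_buf, *, delimiter: str = ",",
                       sample_column: str = "sample_id",
                       date_column: str = "date") -> dict[str, DailySeries]:
    """Read long-format daily weather (sample_id, date, 10 named columns)."""
    df = pd.read_csv(path_or_buf, sep=delimiter)
    value_cols = [c for c in df.columns if c not in (sample_column, date_column)]
    if len(value_cols) != 10:
        raise SchemaError(f"expected 10 meteorological columns, got {len(value_cols)}")
    out: dict[str, DailySeries] = {}
    for sid, grp in df.groupby(sample_column, sort=False):
        grp = grp.sort_values(date_column)
        out[str(sid)] = DailySeries(str(grp[date_column].iloc[0]),
                                    str(grp[date_column].iloc[-1]),
                                    grp[value_cols].to_numpy(dtype=float))
    return out


def table_to_csv_string(table: FeatureTable, **kw) -> str:
    buf = io.StringIO()
    write_table(table, buf, **kw)
    return buf.getvalue()
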