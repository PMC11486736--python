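"""Synthetic multi-environment maize trial tables.

Emulates the statistical structure the bipartite network exploits: a block of
aggregated weather features (per-window means and variances, correlated with
each other and shifted per planting-location group), a block of trait
features that are linear functions of weather plus independent noise (so the
weather <-> trait correlation carries information for imputation), a subset
of traits coarsened to positive integer category labels, a yield that is a
linear + pairwise-interaction function of selected weather and trait latents
with group-scaled Gaussian noise, and power-law-imbalanced location groups.

The noiseless yield signal is standardized to unit variance, so the true
(population) R^2 of the generative model is available in closed form:

    R^2 = 1 / (1 + sigma_y^2 * mean_i(mult_{g(i)}^2))

where mult_g is the per-group residual-scale multiplier. The default
sigma_y = 0.5 with unit multipliers gives R^2 = 0.8.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .tabular_io import (CATEGORICAL, CONTINUOUS, ColumnSpec, FeatureTable,
                         read_table, write_table)

__all__ = ["SimConfig", "GroundTruth", "simulate_trial_data",
           "simulate_dataset", "apply_missingness", "write_fixture",
           "read_fixture", "group_sizes", "true_yield_r2"]

YIELD_MEAN = 600.0   # kg/acre scale of the simulated yields
YIELD_SCALE = 80.0


@dataclass
class SimConfig:
    n_samples: int = 500
    n_weather: int = 20          # aggregated dims: 10 window means + 10 variances
    n_traits: int = 20
    n_categorical: int = 5       # trailing trait columns coarsened to labels
    n_cat_levels: int = 4
    n_groups: int = 5
    group_skew: float = 1.5      # power-law exponent on group sizes
    group_weather_shift: float = 1.0
    weather_corr: float = 0.5    # equicorrelation within the weather block
    rho: float = 0.6             # weather -> trait correlation strength
    n_signal_weather: int = 6    # columns entering the yield signal
    n_signal_traits: int = 6
    n_interactions: int = 4      # pairwise interaction terms in the signal
    sigma_y: float = 0.5         # residual sd on the unit-variance signal
    group_noise_multipliers: list[float] | None = None
    missing_rate: float = 0.18
    row_missing_frac: float = 0.35  # fraction of rows carrying the deletions
    mechanism: str = "MCAR"
    mnar_strength: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mechanism not in ("MCAR", "MNAR"):
            raise ValueError("mechanism must be MCAR or MNAR")
        if self.n_groups > self.n_samples:
            raise ValueError("more groups than samples")
        if self.sigma_y <= 0:
            raise ValueError("sigma_y must be positive")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.n_categorical > self.n_traits:
            raise ValueError("n_categorical exceeds n_traits")
        if not 0 < self.row_missing_frac <= 1:
            raise ValueError("row_missing_frac must be in (0, 1]")
        if self.missing_rate / self.row_missing_frac > 0.95:
            raise ValueError("missing_rate / row_missing_frac exceeds 0.95")


@dataclass
class GroundTruth:
    """Everything the generator knows that the model must not see."""

    values: np.ndarray            # complete n x (m+1) matrix, no missing cells
    signal: np.ndarray            # unit-variance noiseless yield signal
    groups: np.ndarray
    deletion_mask: np.ndarray     # True where a cell was deleted
    config: SimConfig


def group_sizes(config: SimConfig) -> np.ndarray:
    """Power-law sizes, descending, each >= 1, summing to n_samples."""
    raw = np.arange(1, config.n_groups + 1, dtype=float) ** (-config.group_skew)
    sizes = np.maximum(1, np.floor(raw / raw.sum() * config.n_samples)).astype(int)
    sizes[0] += config.n_samples - sizes.sum()
    return sizes


def _multipliers(config: SimConfig) -> np.ndarray:
    if config.group_noise_multipliers is None:
        return np.ones(config.n_groups)
    m = np.asarray(config.group_noise_multipliers, dtype=float)
    if len(m) != config.n_groups:
        raise ValueError("group_noise_multipliers length != n_groups")
    return m


def true_yield_r2(config: SimConfig) -> float:
    """Closed-form population R^2 of the generative yield model."""
    sizes = group_sizes(config)
    mult2 = _multipliers(config) ** 2
    wbar = float((sizes * mult2).sum() / sizes.sum())
    return 1.0 / (1.0 + config.sigma_y**2 * wbar)


def _column_schema(config: SimConfig) -> list[ColumnSpec]:
    half = config.n_weather // 2
    names = ([f"wx_mean_{k+1:02d}" for k in range(half)]
             + [f"wx_var_{k+1:02d}" for k in range(config.n_weather - half)]
             + [f"trait_{k+1:02d}" for k in range(config.n_traits)])
    n_cont_traits = config.n_traits - config.n_categorical
    specs = [ColumnSpec(nm, CONTINUOUS) for nm in names[:config.n_weather + n_cont_traits]]
    for nm in names[config.n_weather + n_cont_traits:]:
        specs.append(ColumnSpec(nm, CATEGORICAL,
                                {str(k): k for k in range(1, config.n_cat_levels + 1)}))
    specs.append(ColumnSpec("yield", CONTINUOUS))
    return specs


def simulate_trial_data(config: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate one complete (no missing cells) trial table plus ground truth."""
    n, w, t = config.n_samples, config.n_weather, config.n_traits
    r_struct = np.random.default_rng([config.seed, 11])
    r_noise = np.random.default_rng([config.seed, 13])

    sizes = group_sizes(config)
    groups = np.repeat([f"loc_{g+1}" for g in range(config.n_groups)], sizes)
    gidx = np.repeat(np.arange(config.n_groups), sizes)

    # weather: equicorrelated Gaussian block + per-group mean shift
    c = config.weather_corr
    shared = r_noise.standard_normal((n, 1))
    weather = np.sqrt(c) * shared + np.sqrt(1 - c) * r_noise.standard_normal((n, w))
    shifts = r_struct.standard_normal((config.n_groups, w)) * config.group_weather_shift
    weather = weather + shifts[gidx]

    # trait latents: rho-weighted unit-variance weather projections + noise
    proj = r_struct.standard_normal((w, t))
    proj /= np.linalg.norm(proj, axis=0, keepdims=True)
    weather_c = weather - weather.mean(axis=0)
    wproj = weather_c @ proj
    std = wproj.std(axis=0)
    std[std == 0] = 1.0
    latents = config.rho * wproj / std \
        + np.sqrt(1 - config.rho**2) * r_noise.standard_normal((n, t))

    # yield signal: linear + pairwise interactions on selected columns
    wsel = r_struct.choice(w, size=min(config.n_signal_weather, w), replace=False)
    tsel = r_struct.choice(t, size=min(config.n_signal_traits, t), replace=False)
    design = np.hstack([weather[:, wsel], latents[:, tsel]])
    coef = r_struct.normal(0, 1, design.shape[1])
    signal = design @ coef
    for _ in range(config.n_interactions):
        a, b = r_struct.choice(design.shape[1], size=2, replace=False)
        signal = signal + 0.5 * r_struct.normal(0, 1) * design[:, a] * design[:, b]
    signal = (signal - signal.mean()) / signal.std()

    mult = _multipliers(config)[gidx]
    noise = r_noise.standard_normal(n) * config.sigma_y * mult
    yields = YIELD_MEAN + YIELD_SCALE * (signal + noise)

    # coarsen trailing traits to equiprobable quantile-bin labels 1..L
    traits = latents.copy()
    n_cont = t - config.n_categorical
    for j in range(n_cont, t):
        edges = np.quantile(latents[:, j],
                            np.linspace(0, 1, config.n_cat_levels + 1)[1:-1])
        traits[:, j] = np.digitize(latents[:, j], edges) + 1

    values = np.hstack([weather, traits, yields[:, None]])
    mask = np.ones_like(values, dtype=bool)
    table = FeatureTable(values, mask, _column_schema(config), groups)
    truth = GroundTruth(values.copy(), signal, groups.copy(),
                        np.zeros_like(mask), config)
    return table, truth


def apply_missingness(table: FeatureTable, rate: float, mechanism: str = "MCAR",
                      seed: int = 0, mnar_strength: float = 2.0,
                      row_frac: float = 1.0,
                      columns: np.ndarray | None = None
                      ) -> tuple[FeatureTable, np.ndarray]:
    """Delete feature cells (never yield) at the given overall rate.

    MCAR deletes each observed feature cell independently; MNAR makes the
    deletion probability increase with the cell's standardized value through
    a logistic link centred so the average rate is preserved approximately.

    With `row_frac` < 1 the deletions concentrate in a value-independent
    random subset of rows (per-cell rate `rate / row_frac` there), emulating
    the row-clustered missingness of real trial records where most rows are
    fully complete while affected rows lose many traits at once. `columns`
    (bool per column) restricts which columns may lose cells — trial records
    lose trait values, never the weather aggregates, so the generator passes
    the trait block here.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if mechanism not in ("MCAR", "MNAR"):
        raise ValueError("mechanism must be MCAR or MNAR")
    if not 0 < row_frac <= 1:
        raise ValueError("row_frac must be in (0, 1]")
    rng = np.random.default_rng([seed, 17])
    out = table.copy()
    n, p = out.values.shape
    feat = np.zeros((n, p), dtype=bool)
    feat[:, :-1] = out.mask[:, :-1]
    if columns is not None:
        feat &= np.asarray(columns, dtype=bool)[None, :]

    if rate == 0:
        return out, np.zeros((n, p), dtype=bool)

    cell_rate = min(rate / row_frac, 0.999)
    if mechanism == "MCAR":
        prob = np.full((n, p), cell_rate)
    else:
        vals = np.nan_to_num(out.values, nan=0.0)
        mu = vals[:, :-1][feat[:, :-1]].mean() if feat.any() else 0.0
        sd = vals[:, :-1][feat[:, :-1]].std() if feat.any() else 1.0
        z = (vals - mu) / (sd if sd > 0 else 1.0)
        logit0 = np.log(cell_rate / (1 - cell_rate))
        prob = 1.0 / (1.0 + np.exp(-(logit0 + mnar_strength * z)))
        # recentre so the mean deletion probability stays near the target
        prob *= cell_rate / prob[feat].mean()
        prob = np.clip(prob, 0, 0.999)

    if row_frac < 1:
        affected = rng.random(n) < row_frac
        prob = prob * affected[:, None]

    delete = feat & (rng.random((n, p)) < prob)
    out.values[delete] = np.nan
    out.mask[delete] = False
    return out, delete


def simulate_dataset(config: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Complete generation pipeline: simulate, then delete traits per config."""
    table, truth = simulate_trial_data(config)
    trait_cols = np.zeros(table.values.shape[1], dtype=bool)
    trait_cols[config.n_weather:config.n_weather + config.n_traits] = True
    table, deleted = apply_missingness(table, config.missing_rate,
                                       config.mechanism, config.seed,
                                       config.mnar_strength,
                                       config.row_missing_frac,
                                       columns=trait_cols)
    truth.deletion_mask = deleted
    return table, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(table: FeatureTable, truth: GroundTruth, directory) -> list[Path]:
    """Emit table.csv, truth.csv and config.yaml; read_table round-trips."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table_path = directory / "table.csv"
    truth_path = directory / "truth.csv"
    config_path = directory / "config.yaml"

    write_table(table, table_path)
    complete = FeatureTable(truth.values, np.ones_like(truth.deletion_mask),
                            table.column_schema, truth.groups)
    write_table(complete, truth_path)
    with open(config_path, "w") as fh:
        yaml.safe_dump(asdict(truth.config), fh)
    return [table_path, truth_path, config_path]


def read_fixture(directory) -> tuple[FeatureTable, FeatureTable, SimConfig]:
    """Load (masked table, complete truth table, config) from a fixture dir."""
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        config = SimConfig(**yaml.safe_load(fh))
    schema = {c.name: c.kind for c in _column_schema(config)}
    table = read_table(directory / "table.csv", schema, group_column="group")
    truth = read_table(directory / "truth.csv", schema, group_column="group")
    return table, truth, config
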