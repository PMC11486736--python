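# Methods

## Problem

Multi-environment maize trials record, per planting sample, a block of
meteorological aggregates, a block of phenotypic traits, and the measured
yield (kg/acre). Trait cells are frequently missing — lodging, seed-supply
failures, recording errors — and missingness clusters by row: most samples
are complete while affected samples lose many traits at once. Sample counts
are imbalanced across planting locations. The package treats trait
imputation and yield prediction as one problem: predicting the value of a
cell in the observations × features table.

## Model

The table becomes a complete bipartite graph. Observation nodes N_i (one per
row) face feature nodes F_j (one per column, the yield included), every pair
is connected, and the edge (i, j) carries the z-scored cell value as a
scalar weight — 0 when the cell is missing. Feature nodes are initialized
with one-hot vectors of length m+1; observation nodes with their 0/1
observed-cell indicator.

Each graph update layer does two things:

1. **Node update.** For every node i,
   `V_i' = ReLU(L_B(Con[ agg_{j∈φ(i)} ReLU(L_A(Con[V_j, e_ij])), V_i ]))`
   where φ(i) is the opposite node set, L_A and L_B are affine maps shared
   by both node types, and `agg` is the degree-normalized sum (see
   *Numerical choices*). Inverted dropout (p = 0.1) is applied to updated
   node embeddings during training.
2. **Edge update.** `e_ij' = Con[V_i', V_j', e_ij]` — pure concatenation, no
   projection, so the edge dimension grows 1 → 2h+1 → 4h+1 → 6h+1 across
   the default three layers (h = 64 is the hidden width).

A two-layer head maps `Con[V_i^L, V_j^L]` for any queried cell to a scalar:
missing-trait imputation (j ≤ m) and yield prediction (j = m+1) are the
same decoding applied to different cells. Categorical trait predictions are
rounded to the nearest valid label after the inverse z-transform.

Because the edge update never mixes components, the layer-l edge embedding
is exactly `[V_i^l, V_j^l, …, V_i^1, V_j^1, e_ij^0]`. Every per-edge affine
map therefore decomposes into per-node affine maps plus a rank-one term in
the raw edge weight, broadcast over the n×(m+1) edge grid. The
implementation computes it that way — O(nodes·edge_dim) instead of
O(edges·edge_dim) work — and a literal per-node loop implementation in the
test suite confirms the two routes agree to 1e-5.

The network runs on a small reverse-mode autodiff core (`bgyield.autograd`)
written for this package: broadcast arithmetic, 2-D matmul, ReLU,
reductions, gather, and an Adam optimizer. Gradients are checked against
central finite differences in the test suite.

## Loss

Training minimizes a gradient-harmonized L1 loss

    L_GHM = (1/N) Σ_i [ |d_i| + |d_i| / sqrt(d_i² + α²) ],   d_i = ŷ_i − y_i

with α = 0.3 on z-scored targets. The second term saturates at 1 for
residuals ≫ α and behaves like |d|/α for residuals ≪ α, so it boosts the
gradient of small-residual samples relative to plain L1 — samples from
thinly represented locations, whose residuals the model would otherwise
trade away, keep influence. As α → ∞ the loss tends to plain L1. Plain L1
and L2 are available for the ablation grid, and α is configurable.

A signed variant with `d_i` in the second numerator is provided for
completeness but is not the default: for under-predictions its two terms
cancel and the per-sample loss *vanishes* as d → −∞, so as a training
objective it rewards predicting arbitrarily low values. The two variants
agree for non-negative residuals.

## Training protocol

* **Split rule.** Rows with ≤ 1 missing feature train the model; rows with
  ≥ 2 are held out (rows with exactly 2, which the rule's two stated
  criteria leave unassigned, go to the held-out side so the training
  criterion holds exactly). Held-out rows' yield edges are zeroed and
  excluded from supervision before any message passing; an assertion in the
  training loop re-checks this every epoch.
* **Normalization.** Per-column z-score with population σ, fit on training
  rows' observed cells only and frozen; metrics are reported after the
  inverse transform, in kg/acre.
* **Self-supervision by row-clustered re-hiding.** Each epoch, a random
  half of the training rows is degraded to look like a sparse row: a
  per-row random share (30–70%) of their observed missingness-prone cells
  (the columns that actually lose values in the table — traits, not
  weather) is hidden, together with the row's yield edge. The loss is
  computed exactly on the hidden cells: the yield term on hidden yields,
  plus λ = 0.3 times the same loss on hidden feature cells. The network
  therefore never merely reads a row's own value back off an input edge,
  and it trains on the many-traits-missing patterns it must handle at
  evaluation time. Earlier iid cell-level re-hiding produced models that
  only ever saw nearly complete rows and failed on sparse ones.
* **Optimization.** Full-graph Adam, flat lr 3·10⁻³, 500 epochs by default
  (20 000 available by config for the full-scale protocol). Early stopping
  watches an exponentially smoothed loss (the raw series is noisy because
  every epoch re-hides a fresh pattern). Cosine annealing and Polyak weight
  averaging are available but off by default: on held-out yield R² across
  three seeds both consistently underperformed the flat schedule — the
  sustained step size appears to act as useful exploration alongside the
  re-hiding noise. All randomness flows from one seed through named
  substreams (init, dropout, re-hiding); seeded runs reproduce
  bit-for-bit.
* **Trait-only variant.** For the pure-imputation benchmark the yield
  feature node is removed and the re-hidden feature-cell loss is the only
  signal.

## Synthetic trial generator

No trial dataset of this kind is publicly deposited, so the generator
produces tables with the statistical structure the method assumes:

* **Weather block** (20 columns, named `wx_mean_*` / `wx_var_*`):
  equicorrelated Gaussian (ρ_w = 0.5) plus a per-location-group mean shift
  (scale 1.0) — locations differ systematically in climate.
* **Trait block** (20 columns): each trait latent is ρ = 0.6 times a
  unit-variance projection of the weather block plus independent noise, so
  traits are partially predictable from weather — the correlation the
  message passing exploits. The last 5 traits are coarsened into
  equiprobable quantile-bin labels 1..4 (categorical traits such as axis
  color are label-encoded integers).
* **Yield**: a linear function of 6 weather and 6 trait latents plus 4
  pairwise interactions, standardized to unit variance, then
  `yield = 600 + 80·(signal + noise)` with noise sd σ_y·mult_g per group.
  With the signal at unit variance the population R² is
  `1 / (1 + σ_y² · mean(mult²))` in closed form; the default σ_y = 0.5
  with unit multipliers gives R² = 0.8.
* **Groups**: power-law sizes (exponent 1.5, 5 groups by default) emulate
  the dense-vs-sparse planting-region imbalance; the imbalance fixture for
  loss comparisons uses 4 groups with the smallest ~10× smaller and a 2×
  residual scale.
* **Missingness**: MCAR deletes observed trait cells via a value-independent
  row-clustered scheme — a random 35% of rows carries all deletions at
  per-cell rate `rate/0.35` — so ~60% of rows stay complete while affected
  rows lose roughly half their traits, matching the row-clustered pattern
  of real trial records and giving the split rule a meaningful partition
  (iid cell deletion at 18% over 40 columns would leave *no* row with ≤ 1
  missing feature). Setting `row_frac = 1` recovers plain iid deletion,
  which is what the random-deletion benchmark uses. MNAR raises a cell's
  deletion probability with its standardized value through a logistic link
  recentred to preserve the average rate. The yield column is never deleted
  by this mechanism; hiding test yields is the training harness's job.

What the generator does **not** emulate: real weather marginals and their
seasonality, cultivar genetics, spatial autocorrelation between
neighbouring trial stations beyond the group mean shifts, and measurement
error in the yield itself. Passing recovery tests on these tables shows the
method can exploit cross-block correlation under realistic missingness —
not that it matches any particular real-world accuracy figure.

## Evaluation

MAE, RMSE and R² = 1 − SS_res/SS_tot, computed globally and per location
group, always in original yield units. The random-deletion benchmark
deletes feature cells of complete rows uniformly at random at 10/20/30%,
imputes with column mean, column median, k-nearest-rows (k = 5,
nan-Euclidean distances via scikit-learn's KNNImputer) and the trait-only
network, and scores MAE on the deleted cells only. The ablation grid trains
one model per configuration over {dropout off/on} × {2/3/4 layers} ×
{L1, L2, GHM(α ∈ 0.3/0.5/0.7)} on a shared split and seed — ten reported
rows, eight unique runs since the base configuration serves three rows.

## Numerical choices and defaults

| Parameter | Default | Why |
|---|---|---|
| hidden width h | 64 | capacity/runtime balance at desk scale |
| update layers | 3 | the architecture's stated depth; ablation covers 2/4 |
| dropout p | 0.1 | the architecture's stated rate |
| neighbor aggregation | degree-normalized sum | raw summation over a complete bipartite graph multiplies activation scale by the degree (n for feature nodes) at every layer; at n = 500 initial losses reach 1e5 and optimization stalls. The raw sum remains available (`aggregate="sum"`) and is oracle-tested. |
| activation | ReLU | ecosystem default for this family |
| α (GHM) | 0.3 | stated operating point; 0.5/0.7 in the ablation |
| Adam lr | 3e-3, flat | 1e-3 underfits at a 500-epoch desk budget; decay schedules underperformed |
| epochs | 500 (cap 20 000) | desk-scale default; early stop on smoothed plateau |
| λ (re-hidden cell loss) | 0.3 | balances yield vs imputation gradients |
| sim n, m | 500, 40 (20+20) | the study's dimensionality at reduced sample count |

Degenerate inputs: zero-variance columns abort normalization with the
column named; all-missing columns abort baseline imputation; a NaN training
loss aborts with the epoch number; empty train or test partitions warn
rather than fail (a fully complete table is legal for the trait-only
variant).

## Known limitations

* Test-set R² at desk scale (n = 500) sits far below the ceiling a 13k-row
  table would allow; at these sizes run-to-run spread across seeds is a few
  hundredths to tenths of R².
* The edge-concatenation growth law makes parameters grow quadratically
  with depth; beyond ~4 layers a projection would be needed.
* Whole-graph batching keeps memory O(n·m·h); fine to tens of thousands of
  rows, not millions.
* The signed (as-printed) GHM variant is unusable as an objective (see
  *Loss*); conclusions about GHM here rest on the absolute variant.
* On the imbalanced-group fixture the gradient-harmonized loss does **not**
  protect the worst location group: across seeds its worst-group test MAE
  runs 10–25% above plain L1's. The mechanism is structural — the term's
  gradient a²/(d²+α²)^{3/2} boosts small-residual (majority-group) samples
  and leaves large-residual (noisy minority) samples at plain-L1 weight, so
  relative to L1 the minority group is deprioritized. The test recording
  this expectation is kept and currently fails; treat GHM's group-level
  benefit as an open question rather than a property of this
  implementation.
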