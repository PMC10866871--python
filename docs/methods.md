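# Methods

## The prediction procedure

`seqstack` treats temporal link prediction as supervised classification of
dyads. For a target layer G_L, each dyad's covariates are the 41 static
topological features evaluated on each of the q layers preceding a label
layer and concatenated in time order (oldest block first, columns suffixed
`@t-3 … @t-1`; the observed-target block, when present, is `@t-0`). Labels
are edge/non-edge indicators in the label layer. Training uses the u−q
label layers before the target (plus one extra group in the
partially-observed setting), so the training set is exactly u−q (resp.
u−q+1) times the test set. A random forest maps stacked vectors to scores;
performance is the AUC of those scores on a balanced sample of held-out
target-layer dyads.

The method assumes: a fixed, fully known node universe (isolates are real
nodes, not missing data); simple, undirected, unweighted layers; and
pre-binned time (converting raw timestamps into layers is the caller's
responsibility). Predictions are made for a single designated target layer
per run — any layer with at least u predecessors may be designated.

### Leakage discipline

Dyad folds are defined once over the whole node universe, stratified so
that each fold carries an equal share (±1) of the target layer's edges and
of its non-edges. In the partially-observed setting every feature that
involves the target layer is computed on the *observed graph* — the target
layer restricted to training-fold dyads — for training and testing alike.
Consequently deleting all test-fold edges from G_L changes test labels but
not a single feature value, which the test suite asserts bit-exactly. The
earlier label layers of the partial setting are masked with the same fold
assignment, mimicking test-time conditions. A consequence of this protocol
(inherent to it, not an implementation choice) is that training-group
labels and the masked label-layer features are computed from the same fold
restriction; the forest therefore sees an optimistic view of the
`@t-0` block during training. In practice the prior-layer blocks dominate
and measured performance stays near the oracle bound.

### Parameters

| parameter | default | notes |
| --- | --- | --- |
| u (search variable) | 6 | layers back available for training; u > q |
| q (flow variable) | 3 | consecutive layers per stacked vector |
| n_folds | 5 | 20% of dyads held out per test fold |
| n_pos | 10,000 | positives (and negatives) sampled with replacement per group |
| repeats | 10 | randomized re-partitions; 10 × 5 folds = 50 runs |
| forest | 500 trees, √d features/split, leaf ≥ 1 | optional small grid selected by F-measure on a 20% slice |
| rank r | min(16, n−1) | truncation rank of the low-rank feature block |
| LP ε | 0.01 | damping of the cubic term in the local path index |
| Katz α | 0.9/λ_max | spectral-radius-safe; iterative tolerances 1e−8 |

The fold partition is redrawn in every repeat (the alternative — one
partition reused across repeats — would make the 50 runs less independent).
One master seed drives everything through `numpy.random.SeedSequence`
spawning: per repeat a partition stream, per (repeat, fold) a sampling/
classifier stream. Identical seeds give bit-identical designs and AUCs.

## The 41-feature bank

Columns are ordered: 5 global (edge count m, density, transitivity NT,
mean local clustering, diameter ND), 8 pairwise (CN, JC, AA, RA, PA, LHN,
SP, LP), 6 low-rank (LRA, dLRA, mLRA and their `-approx` variants), then
11 node features for each endpoint of the dyad, i-side before j-side with
i < j (DC, EC, KC, PR, BC, CC, LC, AND, LCC, core number, triangles). The
exact name list is a versioned contract (`FEATURE_NAMES`) and is
regression-tested.

Numerical conventions, chosen so that every entry is finite:

- shortest path between disconnected dyads is capped at n; the diameter of
  a disconnected graph is that of its largest component (0 if edgeless);
- vacuous node definitions are 0: closeness/average-neighbor-degree of an
  isolated node, clustering of a degree-<2 node; on a completely edgeless
  layer every feature is 0 except SP = n;
- the low-rank block uses the rank-r truncated SVD Â of the dense
  adjacency matrix: LRA = Â_ij, dLRA = ⟨Â_·i, Â_·j⟩, mLRA = the mean of
  Â entries over rows N(i) ∪ N(j) at columns j and i; `-approx` variants
  recompute all three after clipping negative entries of Â to zero;
- "LC" is implemented as load centrality, the closest standard measure to
  the acronym "local centralities"; the column is clearly named, so a
  different interpretation would be a one-line substitution;
- eigenvector centrality comes from a dense symmetric eigensolve (leading
  eigenvector, absolute value, unit norm) rather than power iteration, so
  it cannot stall on disconnected layers; Katz solves its linear system
  directly with α strictly inside the convergence radius.

All per-layer quantities (node tables, pairwise matrices, SVD) are
computed once per graph and cached; dyad rows are lookups. This favors the
regime the package targets — hundreds to a few thousand nodes with many
resampled dyads — over very large sparse graphs.

## Synthetic models and the oracle

Both simulators share the degree-corrected planted partition
P_ij = min(1, θ_i θ_j (c/n)[(1−μ)kδ + μ]) with equal-probability labels,
which keeps the expected mean degree at c for every (μ, k). θ is drawn
i.i.d. Uniform[0.5, 1.5] and renormalized to mean 1 — mild, bounded degree
heterogeneity (θ ≡ 1 is available by passing an explicit vector). Label
dynamics use uniform redraws; the edge-correlated transition is
copy-or-resample per dyad, the unique rule consistent with "an edge stays
an edge with probability p" while keeping the per-layer marginal
stationary at P_ij. The benchmark grid crosses p ∈ {0.9, 0.8, 0.7}
(community-label) or {0.8, 0.7, 0.6} (edge-correlated) with
μ ∈ {0.1, 0.2, 0.3} and k ∈ {1, 2, 5, 10, 15} at n = 200, 10 layers,
c = 10 — 45 points per variant. With 10 layers and u = 6, the first three
layers only burn in the dynamics.

The oracle conditions on the true latent state: target-layer labels
(community-label) or the previous layer's realized adjacency
(edge-correlated, score p·A^{L−1}_ij + (1−p)·P_ij). Its expected AUC is
enumerated exactly over all ordered pairs of dyads, ties counting one
half, positives weighted by P_d and negatives by 1−P_d — an O(D log D)
computation that avoids re-deriving closed forms and is exact at any n the
package simulates. Self-pairs are included in the enumeration as the
formula is written; their contribution is O(1/D). Because the oracle
conditions on the full latent state, its bound is an upper bound on any
oracle that must marginalize over latent labels in the
completely-unobserved setting — conservative in the right direction for a
dominance check.

What the generators do *not* emulate: heavy-tailed degree sequences,
community size heterogeneity, node arrival/departure, weighted or directed
interactions, and non-stationary dynamics. Passing the synthetic
benchmarks therefore demonstrates correct mechanics and near-optimal
statistical behavior under block structure with temporal coupling, not
performance on any particular real data set.

## Baselines

Temporal common neighbors counts the neighbors shared by a dyad in the
intersection of the q layers before the target; at q = 1 it reduces
exactly to the static CN column. The time-series baseline forecasts each
(dyad, feature) series one step ahead and classifies the forecast vectors
with the same forest. The default forecaster is the least-squares AR(1)
conditional mean — the minimal temporal-dependence model — vectorized
across all series; order (0, 1, 0) is a random walk with drift; other
orders use statsmodels ARIMA per series with a logged fallback to the
series mean on any failure, so the output is always finite. In the
partially-observed setting the observed target-layer features are appended
to the forecast vector.

## Problem sizes in tests and reproduction script

Unit and acceptance tests run at desk scale as the package's own default
validation budget: 100-node realizations, 500–1,000 positives per sampled
set, one randomized repeat of the 5-fold cross-validation, 100–150 trees,
and 3–5 realization seeds per condition; oracle-only checks run at the
full n = 200. The full-scale protocol (n_pos = 10,000, 10 repeats,
500 trees) is the library default and is exercised structurally (group
counts, widths, 50-run bookkeeping) on small networks. The
`benchmark` CLI exposes both scales.

## Known limitations

- Dense n×n linear algebra per layer bounds practical network size to a
  few thousand nodes.
- The time-series ensemble provider retrains per label layer, which is
  slow when used inside the full 50-run protocol.
- AUC near the oracle bound on the temporal SBMs does not certify
  performance on real networks with structure the generators lack (see
  above).
- The partially-observed protocol's training-side view of the `@t-0`
  block is optimistic by construction, as discussed under leakage.
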