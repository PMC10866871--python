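# seqstack

Sequential stacking link prediction for temporal networks.

Many networked systems — social contacts, animal interactions, protein
associations, communication logs — are recorded as a sequence of snapshots
("layers") over a shared set of nodes, and a recurring task is to predict
which pairs of nodes will be linked in a layer that is unobserved or only
partially observed. Temporally-extended versions of topological statistics
(temporal betweenness, temporal closeness, ...) are ambiguous to define and
often prohibitively expensive. `seqstack` instead computes cheap **static**
topological features on each layer separately and lets a supervised learner
discover the temporal structure: for every candidate node pair (dyad) it
concatenates 41 per-layer features over `q` consecutive layers and trains a
random forest on the edge/non-edge labels of the following layer.

## Method in brief

Write the temporal network as G = {G_0, ..., G_L} on nodes 0..n−1, with
G_L the target layer. Two parameters control the design:

- the **flow variable** `q` — how many consecutive layers are concatenated
  into one stacked feature vector (default 3);
- the **search variable** `u` — how far back training may reach
  (default 6, with u > q).

Label layers t = L−u+q, ..., L−1 give u−q training groups: features are
stacked from layers t−q..t−1 and labels come from layer t. In the
**completely-unobserved** setting the feature vector has length 41q and
nothing from G_L is used. In the **partially-observed** setting the dyads
are split into 5 folds (stratified so each fold holds ~20% of the edges);
the target layer's edges among training-fold dyads form an observed graph
G_L^observed whose features are appended as an extra block (41(q+1)
columns), and one extra training group is labeled by G_L^observed itself.
Each group samples 10,000 edges and 10,000 non-edges uniformly with
replacement. Scores are evaluated by AUC — the probability that a random
true edge outranks a random non-edge, ties at ½ — averaged over 50 runs
(10 randomized repeats of the 5-fold cross-validation).

The 41 per-layer features combine 5 global measures (edge count, density,
transitivity, mean local clustering, diameter), 8 dyad scores (common
neighbors, Jaccard, Adamic–Adar, resource allocation, preferential
attachment, Leicht–Holme–Newman, shortest path, local path index), 6
low-rank adjacency-approximation scores, and 11 node centralities for each
endpoint (degree, eigenvector, Katz, PageRank, betweenness, closeness,
load, average neighbor degree, clustering, core number, triangles).

External predictor scores can be appended as additional feature columns
(*Ensemble-Sequential-Stacking*), and two interpretable baselines are
included: temporal common neighbors (neighbors in **all** q preceding
layers) and a time-series baseline that forecasts each feature one step
ahead (AR(1) by default) before classifying.

For validation the package ships two degree-corrected temporal stochastic
block models with dyad probabilities

    P_ij = min(1, θ_i θ_j (c/n) [(1−μ) k δ(g_i, g_j) + μ])

(`c` mean degree, `μ` fraction of uniformly random edges, `k` communities,
`θ` mean-1 degree propensities). The *community-label* variant copies each
node's label between layers with probability `p` (else redraws uniformly);
the *edge-correlated* variant fixes the labels and copies each dyad's
edge state with probability `p` (else redraws from the kernel). Both admit
an **oracle** that scores every dyad with its exact model probability; its
expected AUC, computed by exact enumeration over all dyads, upper-bounds
any predictor and calibrates how close the stacker gets to optimal.

## Worked example

```python
import networkx as nx
import numpy as np
from seqstack import (
    TSBMParams, generate_edge_correlated_tsbm, oracle_scores,
    expected_oracle_auc, StackingConfig, run_sequential_stacking, all_dyads,
)

params = TSBMParams(n=100, L_plus_1=10, k=5, p=0.8, mu=0.1, c=10.0,
                    variant="edge_correlated")
net, labels, used = generate_edge_correlated_tsbm(params, np.random.default_rng(0))

cfg = StackingConfig(seed=0, n_pos=500, classifier_params={"n_estimators": 150})
result = run_sequential_stacking(net, cfg, repeats=1)

prev = nx.to_numpy_array(net.layer(net.L - 1))
oracle = oracle_scores(used, labels, prev)
bound = expected_oracle_auc(oracle.dyad_probs(all_dyads(net.n)))

print(f"Top-Sequential-Stacking mean AUC: {result.mean_auc:.3f}")
print(f"exact oracle AUC bound:           {bound:.3f}")
print(result.importances.nlargest(3, "gini")[["column", "gini"]].to_string(index=False))
```

Output:

```
Top-Sequential-Stacking mean AUC: 0.981
exact oracle AUC bound:           0.985
        column     gini
        SP@t-1 0.100619
LRA-approx@t-1 0.081977
       LRA@t-1 0.080456
```

The stacker lands within 0.004 AUC of the best any algorithm could do on
this model. The importances are interpretable: with edge copy probability
p = 0.8 most edges persist between layers, so the most recent layer's
shortest path (SP@t-1 — equal to 1 exactly when the dyad was an edge) and
low-rank adjacency reconstructions carry the most information.

The same pipeline is available from the shell:

```bash
seqstack simulate --variant edge_correlated --n 100 --k 5 --p 0.8 --mu 0.1 \
    --seed 0 --out net.tsv
seqstack predict --edgelist net.tsv --setting unobserved --repeats 1 \
    --n-pos 500 --seed 0 --metrics metrics.json
seqstack benchmark --variant edge_correlated --scale desk --out bench.csv
```

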