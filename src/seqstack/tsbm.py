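"""Degree-corrected temporal stochastic block models and their oracles.

Two generative models for layered networks, sharing one static kernel: a
degree-corrected planted partition in which nodes carry community labels
``g_i`` in ``0..k-1`` and each dyad (i, j) is an independent Bernoulli edge
with probability

    P_ij = min(1, theta_i * theta_j * (c/n) * [(1 - mu) * k * 1(g_i = g_j) + mu])

where ``c`` is the target mean degree, ``mu`` the fraction of edges placed
uniformly at random on top of the block structure, and ``theta`` per-node
degree propensities with mean 1.  With equal-sized communities this keeps
the expected mean degree at ``c`` regardless of ``mu`` and ``k``.

Temporal coupling comes in two variants:

* **community-label**: each node independently copies its previous-layer
  label with probability ``p``, otherwise redraws it uniformly; every
  layer's edges are then drawn independently given that layer's labels.
* **edge-correlated**: labels are fixed for all time; each dyad copies its
  previous edge/non-edge state with probability ``p``, otherwise redraws
  from the static kernel.  The per-layer marginal stays at ``P_ij``.

The *oracle* scores dyads of the target layer with their ground-truth
connection probabilities given the latent state (target-layer labels for
the community-label model, previous-layer adjacency for the
edge-correlated one).  No predictor can beat it in expectation, and its
expected AUC is computed here by exact enumeration over all dyads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import networkx as nx
import numpy as np

from .temporal_graph import TemporalNetwork

__all__ = [
    "TSBMParams",
    "OracleScores",
    "block_probability",
    "block_probability_matrix",
    "generate_tsbm",
    "generate_community_label_tsbm",
    "generate_edge_correlated_tsbm",
    "draw_theta",
    "oracle_scores",
    "oracle_auc",
    "expected_oracle_auc",
    "parameter_grid",
    "BURN_IN_LAYERS",
]

#: Leading layers that only burn in the dynamics; label layers for training
#: are never taken from them at the default u = 6, q = 3 on 10 layers.
BURN_IN_LAYERS = 3


@dataclass
class TSBMParams:
    """Parameters of a degree-corrected temporal SBM.

    ``p`` is the temporal dependency: the label copy probability in the
    community-label variant and the edge copy probability in the
    edge-correlated variant.
    """

    n: int = 200
    L_plus_1: int = 10
    k: int = 5
    p: float = 0.8
    mu: float = 0.1
    c: float = 10.0
    theta: np.ndarray | None = None  # mean-1 propensities; None -> drawn
    variant: str = "edge_correlated"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0,1], got {self.p}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0,1], got {self.mu}")
        if not 1 <= self.k <= self.n:
            raise ValueError(f"k must be in 1..n, got {self.k}")
        if self.c <= 0:
            raise ValueError(f"mean degree c must be positive, got {self.c}")
        if self.variant not in ("community_label", "edge_correlated"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=np.float64)
            if self.theta.shape != (self.n,):
                raise ValueError("theta must have one entry per node")
            if abs(self.theta.mean() - 1.0) > 1e-9:
                raise ValueError("theta must have mean 1")


@dataclass
class OracleScores:
    """Ground-truth edge probabilities for the target layer.

    ``probs`` is a full symmetric n x n matrix of dyad probabilities (the
    diagonal is unused); ``conditioning`` records which latent state the
    probabilities are conditioned on.
    """

    probs: np.ndarray
    conditioning: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        off = self.probs[~np.eye(self.probs.shape[0], dtype=bool)]
        if off.size and (off.min() < 0.0 or off.max() > 1.0):
            raise ValueError("oracle probabilities must lie in [0,1]")

    def dyad_probs(self, dyads: np.ndarray) -> np.ndarray:
        dy = np.asarray(dyads, dtype=np.int64).reshape(-1, 2)
        return self.probs[dy[:, 0], dy[:, 1]]


def draw_theta(n: int, rng: np.random.Generator) -> np.ndarray:
    """Mild bounded degree heterogeneity: Uniform[0.5, 1.5], renormalized
    to mean exactly 1."""
    theta = rng.uniform(0.5, 1.5, size=n)
    return theta / theta.mean()


def block_probability(
    params: TSBMParams, g_i: int, g_j: int, i: int, j: int
) -> float:
    """Connection probability of dyad (i, j) given community labels."""
    theta = params.theta if params.theta is not None else np.ones(params.n)
    base = params.c / params.n
    mix = (1.0 - params.mu) * params.k * (1.0 if g_i == g_j else 0.0) + params.mu
    return float(min(1.0, theta[i] * theta[j] * base * mix))


def block_probability_matrix(
    params: TSBMParams, labels: np.ndarray
) -> np.ndarray:
    """Full symmetric matrix of dyad probabilities given a label vector."""
    labels = np.asarray(labels, dtype=np.int64)
    theta = params.theta if params.theta is not None else np.ones(params.n)
    same = labels[:, None] == labels[None, :]
    mix = np.where(same, (1.0 - params.mu) * params.k + params.mu, params.mu)
    probs = np.minimum(1.0, np.outer(theta, theta) * (params.c / params.n) * mix)
    np.fill_diagonal(probs, 0.0)
    return probs


def _sample_layer(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Symmetric 0/1 adjacency sample with independent upper-triangle dyads."""
    n = probs.shape[0]
    iu = np.triu_indices(n, k=1)
    draws = rng.random(iu[0].size) < probs[iu]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu] = draws
    return adj + adj.T


def _adj_to_graph(adj: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    n = adj.shape[0]
    g.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    mask = adj[iu] > 0
    g.add_edges_from(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    return g


def _with_theta(params: TSBMParams, rng: np.random.Generator) -> TSBMParams:
    if params.theta is None:
        return replace(params, theta=draw_theta(params.n, rng))
    return params


def generate_community_label_tsbm(
    params: TSBMParams, rng: np.random.Generator
) -> tuple[TemporalNetwork, np.ndarray, TSBMParams]:
    """Simulate the community-label variant.

    Returns the network, the (L+1) x n latent label table, and the
    parameters actually used (with the drawn ``theta`` filled in).
    """
    if params.variant != "community_label":
        raise ValueError("params.variant must be 'community_label'")
    params = _with_theta(params, rng)
    n, layers = params.n, params.L_plus_1
    labels = np.empty((layers, n), dtype=np.int64)
    labels[0] = rng.integers(params.k, size=n)
    for t in range(1, layers):
        copy = rng.random(n) < params.p
        redraw = rng.integers(params.k, size=n)
        labels[t] = np.where(copy, labels[t - 1], redraw)
    graphs = [
        _adj_to_graph(_sample_layer(block_probability_matrix(params, labels[t]), rng))
        for t in range(layers)
    ]
    return TemporalNetwork(n=n, layers=graphs), labels, params


def generate_edge_correlated_tsbm(
    params: TSBMParams, rng: np.random.Generator
) -> tuple[TemporalNetwork, np.ndarray, TSBMParams]:
    """Simulate the edge-correlated variant.

    Returns the network, the fixed length-n label vector, and the
    parameters actually used.  Because a dyad either keeps its previous
    state (probability ``p``) or redraws from the static kernel, the
    marginal edge probability of every layer equals the kernel value.
    """
    if params.variant != "edge_correlated":
        raise ValueError("params.variant must be 'edge_correlated'")
    params = _with_theta(params, rng)
    n, layers = params.n, params.L_plus_1
    labels = rng.integers(params.k, size=n)
    probs = block_probability_matrix(params, labels)
    iu = np.triu_indices(n, k=1)

    adj = _sample_layer(probs, rng)
    graphs = [_adj_to_graph(adj)]
    for _ in range(1, layers):
        keep = rng.random(iu[0].size) < params.p
        redraw = rng.random(iu[0].size) < probs[iu]
        upper = np.where(keep, adj[iu].astype(bool), redraw)
        adj = np.zeros((n, n), dtype=np.int8)
        adj[iu] = upper
        adj = adj + adj.T
        graphs.append(_adj_to_graph(adj))
    return TemporalNetwork(n=n, layers=graphs), labels, params


def generate_tsbm(
    params: TSBMParams, rng: np.random.Generator
) -> tuple[TemporalNetwork, np.ndarray, TSBMParams]:
    """Dispatch on ``params.variant``."""
    if params.variant == "community_label":
        return generate_community_label_tsbm(params, rng)
    return generate_edge_correlated_tsbm(params, rng)


def oracle_scores(
    params: TSBMParams,
    labels: np.ndarray,
    previous_adjacency: np.ndarray | None = None,
) -> OracleScores:
    """Ground-truth target-layer dyad probabilities.

    community-label: ``labels`` must be the target layer's label vector;
    the score is the block probability under those labels.

    edge-correlated: ``labels`` is the fixed label vector and
    ``previous_adjacency`` the realized adjacency of layer L-1; the score
    is ``p * A_prev + (1 - p) * P_block``.
    """
    if params.variant == "community_label":
        probs = block_probability_matrix(params, labels)
        return OracleScores(probs=probs, conditioning="target-layer labels")
    if previous_adjacency is None:
        raise ValueError(
            "edge-correlated oracle requires the previous layer's adjacency"
        )
    base = block_probability_matrix(params, labels)
    prev = np.asarray(previous_adjacency, dtype=np.float64)
    probs = params.p * prev + (1.0 - params.p) * base
    np.fill_diagonal(probs, 0.0)
    return OracleScores(
        probs=probs, conditioning="previous-layer adjacency and fixed labels"
    )


def expected_oracle_auc(probs: np.ndarray) -> float:
    """Expected AUC of scoring dyads by their own edge probabilities.

    With dyad probabilities ``P_d``, a random positive is dyad d with
    probability proportional to ``P_d`` and a random negative is dyad d'
    with probability proportional to ``1 - P_d'``; ties in score count
    one half:

        AUC* = sum_{d,d'} P_d (1-P_d') [1(P_d > P_d') + 1/2 1(P_d = P_d')]
               / (sum_d P_d * sum_d' (1 - P_d'))

    Evaluated exactly in O(D log D) by sorting and cumulative sums over
    the D dyad probabilities.
    """
    p = np.asarray(probs, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("no dyads")
    pos_mass = p.sum()
    neg_mass = (1.0 - p).sum()
    if pos_mass <= 0 or neg_mass <= 0:
        raise ValueError("degenerate probabilities: one class has zero mass")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    neg = 1.0 - ps
    # for each distinct value v: wins = (sum of P_d at v) * (neg mass below v)
    # ties = (sum of P_d at v) * (neg mass at v) / 2
    cum_neg = np.concatenate(([0.0], np.cumsum(neg)))
    uniq, start = np.unique(ps, return_index=True)
    bounds = np.concatenate((start, [ps.size]))
    total = 0.0
    for b, e in zip(bounds[:-1], bounds[1:]):
        pos_here = ps[b:e].sum()
        neg_below = cum_neg[b]
        neg_here = cum_neg[e] - cum_neg[b]
        total += pos_here * (neg_below + 0.5 * neg_here)
    return float(total / (pos_mass * neg_mass))


def oracle_auc(
    oracle: OracleScores, dyads: np.ndarray, labels: np.ndarray
) -> float:
    """Empirical AUC of oracle probabilities on a realized test set."""
    from .evaluation import auc

    return auc(oracle.dyad_probs(dyads), labels)


def parameter_grid(variant: str) -> list[TSBMParams]:
    """The benchmark grid: 45 parameter sets per variant (n=200, 10 layers,
    c=10), crossing three temporal dependencies, three randomness fractions
    and five community counts."""
    if variant == "community_label":
        p_values = (0.9, 0.8, 0.7)
    elif variant == "edge_correlated":
        p_values = (0.8, 0.7, 0.6)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    mu_values = (0.1, 0.2, 0.3)
    k_values = (1, 2, 5, 10, 15)
    return [
        TSBMParams(n=200, L_plus_1=10, k=k, p=p, mu=mu, c=10.0, variant=variant)
        for p, mu, k in product(p_values, mu_values, k_values)
    ]
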