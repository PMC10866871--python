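"""The canonical bank of 41 static topological features for dyads on one layer.

Each temporal layer is summarized, for every dyad (i, j) of interest, by a
fixed 41-column vector combining

* 5 global graph measures (shared by all dyads of the layer),
* 8 pairwise proximity scores for the dyad itself,
* 6 low-rank adjacency-approximation scores for the dyad,
* 11 node-level centralities for i and the same 11 for j (i < j).

The column order and names are part of the package contract
(:data:`FEATURE_NAMES`); the sequential stacker concatenates these blocks
across consecutive layers.

All features are finite by construction: shortest path on a disconnected
dyad is capped at ``n``, the diameter of a disconnected graph is that of
its largest component, and vacuous node definitions (clustering of a
degree-<2 node, closeness or average neighbor degree of an isolated node)
are set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "FEATURE_NAMES",
    "GLOBAL_FEATURES",
    "PAIRWISE_FEATURES",
    "LOWRANK_FEATURES",
    "NODE_FEATURES",
    "FeatureBlock",
    "LayerFeatures",
    "compute_global_features",
    "compute_node_features",
    "compute_pairwise_features",
    "compute_lowrank_features",
    "compute_layer_feature_block",
]

GLOBAL_FEATURES = ["m", "density", "NT", "meanLCC", "ND"]
PAIRWISE_FEATURES = ["CN", "JC", "AA", "RA", "PA", "LHN", "SP", "LP"]
LOWRANK_FEATURES = [
    "LRA",
    "dLRA",
    "mLRA",
    "LRA-approx",
    "dLRA-approx",
    "mLRA-approx",
]
NODE_FEATURES = [
    "DC",
    "EC",
    "KC",
    "PR",
    "BC",
    "CC",
    "LC",
    "AND",
    "LCC",
    "core",
    "tri",
]

#: Canonical ordered names of the 41 per-layer features (versioned contract).
FEATURE_NAMES: list[str] = (
    GLOBAL_FEATURES
    + PAIRWISE_FEATURES
    + LOWRANK_FEATURES
    + [f"{f}_i" for f in NODE_FEATURES]
    + [f"{f}_j" for f in NODE_FEATURES]
)

DEFAULT_LP_EPS = 0.01  # damping of the cubic term in the local path index
DEFAULT_MAX_RANK = 16  # default truncation rank for the low-rank block


class FeatureConvergenceError(RuntimeError):
    """An iterative centrality failed to converge."""


@dataclass
class FeatureBlock:
    """A |dyads| x 41 feature matrix with its dyads and column names."""

    dyads: np.ndarray  # (m, 2) int, i < j
    values: np.ndarray  # (m, 41) float
    names: list[str]

    def __post_init__(self) -> None:
        self.dyads = np.asarray(self.dyads, dtype=np.int64).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.dyads.shape[0], len(self.names)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.dyads.shape[0]} dyads x {len(self.names)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature block contains non-finite entries")

    def to_frame(self, suffix: str = "") -> pd.DataFrame:
        """Export as a DataFrame; ``suffix`` tags layer offset (e.g. '@t-2')."""
        cols = [name + suffix for name in self.names]
        frame = pd.DataFrame(self.values, columns=cols)
        frame.insert(0, "j", self.dyads[:, 1])
        frame.insert(0, "i", self.dyads[:, 0])
        return frame


def _as_dyad_array(dyads) -> np.ndarray:
    arr = np.asarray(list(dyads) if not isinstance(dyads, np.ndarray) else dyads)
    arr = arr.reshape(-1, 2).astype(np.int64)
    if arr.size and np.any(arr[:, 0] == arr[:, 1]):
        raise ValueError("self-dyads are not valid")
    # canonical orientation i < j
    return np.sort(arr, axis=1)


def _adjacency(g: nx.Graph) -> np.ndarray:
    n = g.number_of_nodes()
    A = np.zeros((n, n), dtype=np.float64)
    for u, v in g.edges():
        A[u, v] = 1.0
        A[v, u] = 1.0
    return A


class LayerFeatures:
    """All 41 features of one layer, computed once, indexable by dyad.

    Node, global, pairwise and low-rank quantities are computed for the
    whole graph on construction (dense linear algebra; intended for the
    network sizes this package targets, up to a few thousand nodes), so
    that feature rows for arbitrary dyad samples are cheap lookups.
    """

    def __init__(
        self,
        g: nx.Graph,
        rank: int | None = None,
        lp_eps: float = DEFAULT_LP_EPS,
    ) -> None:
        self.n = g.number_of_nodes()
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if set(g.nodes()) != set(range(self.n)):
            raise ValueError("graph nodes must be 0..n-1")
        self.g = g
        if rank is None:
            self.rank = min(DEFAULT_MAX_RANK, self.n - 1)
        else:
            if not 1 <= rank <= self.n - 1:
                raise ValueError(f"rank must be in 1..n-1, got {rank}")
            self.rank = rank
        self.lp_eps = lp_eps

        self._A = _adjacency(g)
        self._deg = self._A.sum(axis=1)
        self._sp = self._shortest_paths()
        self.global_values = self._globals()
        self.node_values = self._node_table()
        self._pair = self._pairwise_matrices()
        self._lowrank = self._lowrank_matrices()

    # -- per-graph computations -------------------------------------------

    def _shortest_paths(self) -> np.ndarray:
        sp = shortest_path(csr_array(self._A), method="D", unweighted=True)
        sp[~np.isfinite(sp)] = float(self.n)  # disconnected dyads: cap at n
        return sp

    def _globals(self) -> np.ndarray:
        g, n = self.g, self.n
        m = g.number_of_edges()
        density = 2.0 * m / (n * (n - 1))
        if m == 0:
            return np.array([0.0, 0.0, 0.0, 0.0, 0.0])
        nt = nx.transitivity(g)
        mean_lcc = sum(nx.clustering(g).values()) / n
        comps = max(nx.connected_components(g), key=len)
        if len(comps) < 2:
            diam = 0.0
        else:
            idx = np.fromiter(comps, dtype=np.int64)
            diam = float(self._sp[np.ix_(idx, idx)].max())
        return np.array([float(m), density, nt, mean_lcc, diam])

    def _node_table(self) -> np.ndarray:
        g, n, A, d = self.g, self.n, self._A, self._deg
        table = np.zeros((n, len(NODE_FEATURES)), dtype=np.float64)
        if g.number_of_edges() == 0:
            return table

        table[:, 0] = d / (n - 1)  # DC
        table[:, 1] = self._eigenvector_centrality()  # EC
        table[:, 2] = self._katz_centrality()  # KC
        try:
            pr = nx.pagerank(g, alpha=0.85, tol=1e-8, max_iter=1000)
        except nx.PowerIterationFailedConvergence as exc:
            raise FeatureConvergenceError(
                "PageRank failed to converge (tol=1e-8, max_iter=1000)"
            ) from exc
        table[:, 3] = [pr[v] for v in range(n)]
        bc = nx.betweenness_centrality(g, normalized=True)
        table[:, 4] = [bc[v] for v in range(n)]
        cc = nx.closeness_centrality(g)
        table[:, 5] = [cc[v] for v in range(n)]
        lc = nx.load_centrality(g, normalized=True)
        table[:, 6] = [lc[v] for v in range(n)]
        with np.errstate(invalid="ignore", divide="ignore"):
            table[:, 7] = np.where(d > 0, (A @ d) / np.where(d > 0, d, 1), 0.0)
        lcc = nx.clustering(g)
        table[:, 8] = [lcc[v] for v in range(n)]
        core = nx.core_number(g)
        table[:, 9] = [core[v] for v in range(n)]
        tri = nx.triangles(g)
        table[:, 10] = [tri[v] for v in range(n)]
        return table

    def _eigenvector_centrality(self) -> np.ndarray:
        # leading eigenvector of the adjacency matrix, unit Euclidean norm;
        # a dense symmetric eigensolve sidesteps power-iteration stalls
        vals, vecs = np.linalg.eigh(self._A)
        vec = np.abs(vecs[:, int(np.argmax(vals))])
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def _katz_centrality(self) -> np.ndarray:
        lam = float(np.max(np.linalg.eigvalsh(self._A)))
        if lam <= 0:
            return np.zeros(self.n)
        alpha = 0.9 / lam  # spectral-radius-safe damping
        x = np.linalg.solve(
            np.eye(self.n) - alpha * self._A, np.ones(self.n)
        )
        return x / np.linalg.norm(x)

    def _pairwise_matrices(self) -> dict[str, np.ndarray]:
        A, d, n = self._A, self._deg, self.n
        cn = A @ A
        union = d[:, None] + d[None, :] - cn
        with np.errstate(invalid="ignore", divide="ignore"):
            jc = np.where(union > 0, cn / np.where(union > 0, union, 1), 0.0)
            w_aa = np.where(d >= 2, 1.0 / np.log(np.where(d >= 2, d, 2)), 0.0)
            w_ra = np.where(d > 0, 1.0 / np.where(d > 0, d, 1), 0.0)
        aa = (A * w_aa) @ A
        ra = (A * w_ra) @ A
        pa = np.outer(d, d)
        lhn = np.where(pa > 0, cn / np.where(pa > 0, pa, 1), 0.0)
        lp = cn + self.lp_eps * (A @ cn)
        return {
            "CN": cn,
            "JC": jc,
            "AA": aa,
            "RA": ra,
            "PA": pa,
            "LHN": lhn,
            "SP": self._sp,
            "LP": lp,
            "_union": union,
        }

    def _lowrank_matrices(self) -> dict[str, np.ndarray]:
        n = self.n
        if self.g.number_of_edges() == 0:
            zero = np.zeros((n, n))
            return {name: zero for name in LOWRANK_FEATURES}
        u_mat, s, vt = np.linalg.svd(self._A)
        r = self.rank
        ahat = (u_mat[:, :r] * s[:r]) @ vt[:r]
        out: dict[str, np.ndarray] = {}
        for suffix, mat in (("", ahat), ("-approx", np.clip(ahat, 0.0, None))):
            out["LRA" + suffix] = mat
            out["dLRA" + suffix] = mat.T @ mat
            out["mLRA" + suffix] = self._mlra(mat)
        return out

    def _mlra(self, mat: np.ndarray) -> np.ndarray:
        """Mean of ``mat`` entries over rows N(i) u N(j) at columns j and i.

        Vectorized over all dyads via inclusion-exclusion on the neighbor
        union: sum over N(i) u N(j) of column j equals
        (B @ M)[i, j] + diag(B @ M)[j] - sum over N(i) n N(j).
        """
        B = self._A
        C = B @ mat
        diag_c = np.diag(C)
        E = B * mat.T  # E[j, w] = B[j, w] * mat[w, j]
        D = (E @ B.T).T  # D[i, j] = sum over N(i) n N(j) of mat[w, j]
        col_j = C + diag_c[None, :] - D
        total = col_j + col_j.T
        cnt = 2.0 * self._pair["_union"]
        return np.where(cnt > 0, total / np.where(cnt > 0, cnt, 1), 0.0)

    # -- dyad lookup --------------------------------------------------------

    def block(self, dyads) -> FeatureBlock:
        """Assemble the |dyads| x 41 feature matrix for the given dyads."""
        dy = _as_dyad_array(dyads)
        m = dy.shape[0]
        out = np.empty((m, len(FEATURE_NAMES)), dtype=np.float64)
        ii, jj = dy[:, 0], dy[:, 1]
        out[:, : len(GLOBAL_FEATURES)] = self.global_values
        col = len(GLOBAL_FEATURES)
        for name in PAIRWISE_FEATURES:
            out[:, col] = self._pair[name][ii, jj]
            col += 1
        for name in LOWRANK_FEATURES:
            out[:, col] = self._lowrank[name][ii, jj]
            col += 1
        k = len(NODE_FEATURES)
        out[:, col : col + k] = self.node_values[ii]
        out[:, col + k : col + 2 * k] = self.node_values[jj]
        return FeatureBlock(dyads=dy, values=out, names=list(FEATURE_NAMES))


# -- module-level operations (thin wrappers around LayerFeatures) -----------


def compute_global_features(g: nx.Graph) -> np.ndarray:
    """(edge count, density, transitivity, mean local clustering, diameter
    of the largest connected component; 0 for edgeless graphs)."""
    return LayerFeatures(g).global_values.copy()


def compute_node_features(g: nx.Graph) -> np.ndarray:
    """n x 11 table of node centralities in :data:`NODE_FEATURES` order."""
    return LayerFeatures(g).node_values.copy()


def compute_pairwise_features(g: nx.Graph, dyads) -> np.ndarray:
    """|dyads| x 8 matrix of dyad proximity scores (:data:`PAIRWISE_FEATURES`)."""
    lf = LayerFeatures(g)
    dy = _as_dyad_array(dyads)
    cols = [lf._pair[name][dy[:, 0], dy[:, 1]] for name in PAIRWISE_FEATURES]
    return np.stack(cols, axis=1) if dy.size else np.empty((0, 8))


def compute_lowrank_features(g: nx.Graph, rank: int, dyads) -> np.ndarray:
    """|dyads| x 6 matrix of rank-``rank`` SVD approximation scores."""
    lf = LayerFeatures(g, rank=rank)
    dy = _as_dyad_array(dyads)
    cols = [lf._lowrank[name][dy[:, 0], dy[:, 1]] for name in LOWRANK_FEATURES]
    return np.stack(cols, axis=1) if dy.size else np.empty((0, 6))


def compute_layer_feature_block(
    g: nx.Graph, dyads, rank: int | None = None, lp_eps: float = DEFAULT_LP_EPS
) -> FeatureBlock:
    """Full 41-column feature block for ``dyads`` on a single layer."""
    return LayerFeatures(g, rank=rank, lp_eps=lp_eps).block(dyads)
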