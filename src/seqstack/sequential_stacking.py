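"""Sequential stacking of static per-layer features for temporal link prediction.

Given a temporal network ``G_0..G_L`` and a target layer ``G_L``, the
stacker concatenates the 41 static topological features of each dyad over
``q`` consecutive layers and learns, with a random forest, to map that
stacked vector to the dyad's edge/non-edge label in the following layer.
The *search variable* ``u`` (> q) fixes how far back training reaches:
label layers ``L-u+q .. L-1`` give ``u - q`` training groups, and in the
partially-observed setting an extra group labeled by the observed part of
``G_L`` itself.

Two prediction settings are supported:

* *completely unobserved*: no structural information from ``G_L`` is used;
  each stacked vector has ``41 q`` columns.
* *partially observed*: dyads are split into folds once over the node
  universe; the target layer's edges among training-fold dyads form an
  observed graph whose features are appended as one extra 41-column block
  (``41 (q + 1)`` columns).  Test-fold edges of ``G_L`` never contribute
  to any feature, in training or in testing.

Class balance follows a sample-with-replacement protocol: each group draws
``n_pos`` edges and ``n_pos`` non-edges uniformly with replacement from
the dyads allowed to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

from .feature_bank import FEATURE_NAMES, LayerFeatures
from .temporal_graph import TemporalNetwork

__all__ = [
    "COMPLETELY_UNOBSERVED",
    "PARTIALLY_OBSERVED",
    "StackingConfig",
    "LabeledDesign",
    "StackingResult",
    "ProviderError",
    "all_dyads",
    "dyad_index",
    "edge_mask",
    "partition_dyads",
    "sample_balanced_dyads",
    "mask_to_observed",
    "build_training_design",
    "build_test_design",
    "train_stacker",
    "run_sequential_stacking",
]

COMPLETELY_UNOBSERVED = "completely_unobserved"
PARTIALLY_OBSERVED = "partially_observed"
SETTINGS = (COMPLETELY_UNOBSERVED, PARTIALLY_OBSERVED)

DEFAULT_CLASSIFIER_PARAMS = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "min_samples_leaf": 1,
}


class ProviderError(RuntimeError):
    """An ensemble score provider returned unusable scores."""


@dataclass
class StackingConfig:
    """Configuration of one sequential-stacking run.

    ``u`` and ``q`` follow the search/flow-variable scheme (u > q >= 1);
    defaults reproduce the standard protocol: u=6, q=3, 5 dyad folds,
    10,000 positives per sampled set.
    """

    u: int = 6
    q: int = 3
    setting: str = COMPLETELY_UNOBSERVED
    n_folds: int = 5
    n_pos: int = 10_000
    seed: int = 0
    classifier_params: dict = field(default_factory=dict)
    rank: int | None = None
    lp_eps: float = 0.01
    features: list[str] | None = None  # optional subset of FEATURE_NAMES

    def __post_init__(self) -> None:
        if not self.u > self.q >= 1:
            raise ValueError(f"need u > q >= 1, got u={self.u}, q={self.q}")
        if self.n_folds < 2:
            raise ValueError(f"need n_folds >= 2, got {self.n_folds}")
        if self.n_pos < 1:
            raise ValueError(f"need n_pos >= 1, got {self.n_pos}")
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        if self.features is not None:
            unknown = set(self.features) - set(FEATURE_NAMES)
            if unknown:
                raise ValueError(f"unknown feature names: {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features) if self.features else list(FEATURE_NAMES)

    @property
    def n_groups_extra(self) -> int:
        return 1 if self.setting == PARTIALLY_OBSERVED else 0


@dataclass
class LabeledDesign:
    """A stacked feature matrix with labels, dyads and group provenance."""

    X: np.ndarray  # (rows, 41q [+41] [+providers])
    y: np.ndarray  # (rows,) in {0, 1}
    dyads: np.ndarray  # (rows, 2)
    group_id: np.ndarray  # (rows,) which training group each row came from
    columns: list[str]

    def __post_init__(self) -> None:
        rows = self.X.shape[0]
        if not (len(self.y) == rows == self.dyads.shape[0] == len(self.group_id)):
            raise ValueError("inconsistent design row counts")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names do not match design width")


@dataclass
class StackingResult:
    """Cross-validated output of :func:`run_sequential_stacking`."""

    mean_auc: float
    aucs: list[float]
    mean_ap: float
    aps: list[float]
    importances: pd.DataFrame  # columns: column, feature, layer_offset, gini
    scores: pd.DataFrame  # columns: i, j, score, label, fold, repeat
    config: StackingConfig


# -- dyad bookkeeping -------------------------------------------------------


def all_dyads(n: int) -> np.ndarray:
    """All unordered dyads (i < j) in canonical lexicographic order."""
    iu = np.triu_indices(n, k=1)
    return np.stack(iu, axis=1).astype(np.int64)


def dyad_index(n: int, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Canonical index of dyad (i, j), i < j, in :func:`all_dyads` order."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


def edge_mask(g: nx.Graph, n: int) -> np.ndarray:
    """Boolean mask over canonical dyads marking the edges of ``g``."""
    mask = np.zeros(n * (n - 1) // 2, dtype=bool)
    if g.number_of_edges():
        uv = np.array([(min(u, v), max(u, v)) for u, v in g.edges()])
        mask[dyad_index(n, uv[:, 0], uv[:, 1])] = True
    return mask


# -- fold partition and sampling -------------------------------------------


def partition_dyads(target: nx.Graph, n_folds: int, seed: int) -> np.ndarray:
    """Assign every dyad of the node universe to one of ``n_folds`` folds.

    The split is stratified on the target layer: its edges are spread
    across folds with counts differing by at most one, and likewise the
    non-edges, so every fold holds ~1/n_folds of the edges.
    """
    if n_folds < 2:
        raise ValueError(f"need n_folds >= 2, got {n_folds}")
    n = target.number_of_nodes()
    rng = np.random.default_rng(seed)
    is_edge = edge_mask(target, n)
    if is_edge.sum() < n_folds:
        import logging

        logging.getLogger(__name__).warning(
            "target layer has fewer edges (%d) than folds (%d)",
            int(is_edge.sum()),
            n_folds,
        )
    folds = np.empty(is_edge.size, dtype=np.int64)
    for mask in (is_edge, ~is_edge):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def sample_balanced_dyads(
    label_layer: nx.Graph,
    allowed: np.ndarray,
    n_pos: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_pos`` edges and ``n_pos`` non-edges, each uniformly with
    replacement, from the dyads where ``allowed`` is True.

    Returns ``(dyads, labels)`` with positives first; duplicates are kept.
    """
    n = label_layer.number_of_nodes()
    allowed = np.asarray(allowed, dtype=bool)
    is_edge = edge_mask(label_layer, n)
    pos_pool = np.flatnonzero(allowed & is_edge)
    neg_pool = np.flatnonzero(allowed & ~is_edge)
    if pos_pool.size == 0 or neg_pool.size == 0:
        raise ValueError(
            "allowed dyad set must contain at least one edge and one non-edge"
        )
    chosen = np.concatenate(
        [
            rng.choice(pos_pool, size=n_pos, replace=True),
            rng.choice(neg_pool, size=n_pos, replace=True),
        ]
    )
    labels = np.concatenate([np.ones(n_pos, np.int64), np.zeros(n_pos, np.int64)])
    return all_dyads(n)[chosen], labels


def mask_to_observed(layer: nx.Graph, training_mask: np.ndarray) -> nx.Graph:
    """The observed part of a layer: only edges whose dyad is in the
    training folds survive."""
    n = layer.number_of_nodes()
    training_mask = np.asarray(training_mask, dtype=bool)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v in layer.edges():
        a, b = min(u, v), max(u, v)
        if training_mask[dyad_index(n, np.int64(a), np.int64(b))]:
            g.add_edge(a, b)
    return g


# -- feature caching --------------------------------------------------------


class FeatureCache:
    """Memoizes :class:`LayerFeatures` per graph key.

    Prior layers are keyed by their layer index and shared across repeats
    and folds; masked (observed-part) graphs depend on the fold split and
    are keyed by the caller.
    """

    def __init__(self, cfg: StackingConfig) -> None:
        self.cfg = cfg
        self._store: dict = {}

    def get(self, key, g: nx.Graph) -> LayerFeatures:
        if key not in self._store:
            self._store[key] = LayerFeatures(
                g, rank=self.cfg.rank, lp_eps=self.cfg.lp_eps
            )
        return self._store[key]

    def evict_masked(self) -> None:
        """Drop fold-specific (masked-graph) entries; they are only reused
        within one cross-validation run and would otherwise accumulate."""
        self._store = {
            k: v
            for k, v in self._store.items()
            if not (isinstance(k, tuple) and k and k[0] == "masked")
        }


def _feature_selector(cfg: StackingConfig) -> np.ndarray:
    names = cfg.feature_names
    return np.array([FEATURE_NAMES.index(name) for name in names], dtype=np.int64)


def _stacked_columns(cfg: StackingConfig, providers) -> list[str]:
    cols: list[str] = []
    for offset in range(cfg.q, 0, -1):
        cols.extend(f"{name}@t-{offset}" for name in cfg.feature_names)
    if cfg.setting == PARTIALLY_OBSERVED:
        cols.extend(f"{name}@t-0" for name in cfg.feature_names)
    for provider in providers or []:
        cols.append(f"ens:{_provider_name(provider)}")
    return cols


def _provider_name(provider) -> str:
    return getattr(provider, "__name__", provider.__class__.__name__)


def _provider_column(
    provider, net, cfg, dyads, setting, target_layer
) -> np.ndarray:
    scores = np.asarray(
        provider(net, cfg, dyads, setting, target_layer), dtype=np.float64
    )
    if scores.shape != (dyads.shape[0],):
        raise ProviderError(
            f"provider {_provider_name(provider)!r} returned shape "
            f"{scores.shape}, expected ({dyads.shape[0]},)"
        )
    if not np.all(np.isfinite(scores)):
        raise ProviderError(
            f"provider {_provider_name(provider)!r} returned non-finite scores"
        )
    return scores


def _stack_rows(
    net: TemporalNetwork,
    cfg: StackingConfig,
    cache: FeatureCache,
    dyads: np.ndarray,
    label_layer: int,
    masked_graph_and_key,
    providers,
) -> np.ndarray:
    """One group's stacked feature matrix for the given dyads."""
    sel = _feature_selector(cfg)
    blocks = []
    for t in range(label_layer - cfg.q, label_layer):
        lf = cache.get(("layer", t), net.layer(t))
        blocks.append(lf.block(dyads).values[:, sel])
    if masked_graph_and_key is not None:
        key, g_obs = masked_graph_and_key
        lf = cache.get(key, g_obs)
        blocks.append(lf.block(dyads).values[:, sel])
    for provider in providers or []:
        col = _provider_column(
            provider, net, cfg, dyads, cfg.setting, label_layer
        )
        blocks.append(col[:, None])
    return np.hstack(blocks)


# -- design assembly --------------------------------------------------------


def _check_history(net: TemporalNetwork, cfg: StackingConfig, target: int) -> None:
    if target > net.L:
        raise ValueError(f"target layer {target} beyond last layer {net.L}")
    if target < cfg.u:
        raise ValueError(
            f"target layer {target} needs at least u={cfg.u} preceding layers"
        )


def build_training_design(
    net: TemporalNetwork,
    cfg: StackingConfig,
    fold_assignment: np.ndarray,
    test_fold: int,
    rng: np.random.Generator,
    cache: FeatureCache | None = None,
    providers: Sequence[Callable] | None = None,
    target: int | None = None,
    mask_tag=None,
) -> LabeledDesign:
    """Assemble the training design for one (fold split, test fold).

    One group per label layer ``t`` in ``target-u+q .. target-1`` — features
    stacked from layers ``t-q .. t-1`` (plus the observed part of ``G_t``
    in the partially-observed setting) — and, in the partially-observed
    setting, one extra group labeled by the training-fold edges of the
    target layer itself.  Labels are balanced samples from training-fold
    dyads of each group's label layer.
    """
    target = net.L if target is None else target
    _check_history(net, cfg, target)
    cache = cache or FeatureCache(cfg)
    training_mask = fold_assignment != test_fold

    label_layers = list(range(target - cfg.u + cfg.q, target))
    if cfg.setting == PARTIALLY_OBSERVED:
        label_layers.append(target)

    xs, ys, ds, gs = [], [], [], []
    for gid, t in enumerate(label_layers):
        dyads, labels = sample_balanced_dyads(
            net.layer(t), training_mask, cfg.n_pos, rng
        )
        masked = None
        if cfg.setting == PARTIALLY_OBSERVED:
            key = ("masked", t, test_fold, mask_tag)
            masked = (key, mask_to_observed(net.layer(t), training_mask))
        xs.append(
            _stack_rows(net, cfg, cache, dyads, t, masked, providers)
        )
        ys.append(labels)
        ds.append(dyads)
        gs.append(np.full(labels.size, gid, dtype=np.int64))

    return LabeledDesign(
        X=np.vstack(xs),
        y=np.concatenate(ys),
        dyads=np.vstack(ds),
        group_id=np.concatenate(gs),
        columns=_stacked_columns(cfg, providers),
    )


def build_test_design(
    net: TemporalNetwork,
    cfg: StackingConfig,
    fold_assignment: np.ndarray,
    test_fold: int,
    rng: np.random.Generator,
    cache: FeatureCache | None = None,
    providers: Sequence[Callable] | None = None,
    target: int | None = None,
    mask_tag=None,
) -> LabeledDesign:
    """Assemble the test design: balanced labels from test-fold dyads of the
    target layer; features from the ``q`` preceding layers, plus (partially
    observed) the training-fold-masked target layer.  No test-fold edge of
    the target layer contributes to any feature."""
    target = net.L if target is None else target
    _check_history(net, cfg, target)
    cache = cache or FeatureCache(cfg)
    training_mask = fold_assignment != test_fold

    dyads, labels = sample_balanced_dyads(
        net.layer(target), ~training_mask, cfg.n_pos, rng
    )
    masked = None
    if cfg.setting == PARTIALLY_OBSERVED:
        key = ("masked", target, test_fold, mask_tag)
        masked = (key, mask_to_observed(net.layer(target), training_mask))
    X = _stack_rows(net, cfg, cache, dyads, target, masked, providers)
    return LabeledDesign(
        X=X,
        y=labels,
        dyads=dyads,
        group_id=np.zeros(labels.size, dtype=np.int64),
        columns=_stacked_columns(cfg, providers),
    )


# -- classifier -------------------------------------------------------------


def train_stacker(
    design: LabeledDesign, cfg: StackingConfig, rng: np.random.Generator
) -> RandomForestClassifier:
    """Fit the random-forest stacker on a labeled design.

    ``cfg.classifier_params`` overrides the forest hyperparameters; a
    ``"grid"`` entry (list of param dicts) triggers selection by F-measure
    on a held-out 20% slice before refitting on the full design.
    """
    if design.X.shape[0] == 0:
        raise ValueError("empty design")
    if len(np.unique(design.y)) < 2:
        raise ValueError("training design must contain both classes")

    params = dict(DEFAULT_CLASSIFIER_PARAMS)
    params.update(
        {k: v for k, v in (cfg.classifier_params or {}).items() if k != "grid"}
    )
    grid = (cfg.classifier_params or {}).get("grid")
    if grid:
        X_tr, X_val, y_tr, y_val = train_test_split(
            design.X,
            design.y,
            test_size=0.2,
            stratify=design.y,
            random_state=int(rng.integers(2**31)),
        )
        best_f1, best = -1.0, None
        for candidate in grid:
            trial = dict(params)
            trial.update(candidate)
            clf = RandomForestClassifier(
                random_state=int(rng.integers(2**31)), n_jobs=1, **trial
            )
            clf.fit(X_tr, y_tr)
            score = f1_score(y_val, clf.predict(X_val))
            if score > best_f1:
                best_f1, best = score, trial
        params = best

    clf = RandomForestClassifier(
        random_state=int(rng.integers(2**31)), n_jobs=1, **params
    )
    clf.fit(design.X, design.y)
    return clf


# -- full pipeline ----------------------------------------------------------


def run_sequential_stacking(
    net: TemporalNetwork,
    cfg: StackingConfig,
    ensemble_providers: Sequence[Callable] | None = None,
    repeats: int = 10,
    target: int | None = None,
) -> StackingResult:
    """Cross-validated sequential stacking on one temporal network.

    Repeats a randomized fold partition ``repeats`` times; within each
    repeat every fold serves once as the test fold, so the default 10
    repeats of 5-fold cross-validation yield 50 per-run AUC values.  With
    providers, one external-score column per provider is appended to both
    training and test designs (Ensemble-Sequential-Stacking); with none,
    this is Top-Sequential-Stacking.

    Providers are callables ``provider(net, cfg, dyads, setting, layer)``
    returning one finite score per dyad for predicting edges in ``layer``.

    All randomness derives from ``cfg.seed`` through per-(repeat, fold)
    substreams, so results are bit-reproducible.
    """
    from .evaluation import auc, precision_recall

    target = net.L if target is None else target
    _check_history(net, cfg, target)
    cache = FeatureCache(cfg)

    aucs: list[float] = []
    aps: list[float] = []
    importance_rows = []
    score_frames = []
    root = np.random.SeedSequence(cfg.seed)
    for repeat, repeat_ss in enumerate(root.spawn(repeats)):
        part_ss, *fold_ss = repeat_ss.spawn(cfg.n_folds + 1)
        fold_assignment = partition_dyads(
            net.layer(target), cfg.n_folds, int(part_ss.generate_state(1)[0] % 2**31)
        )
        for fold, ss in enumerate(fold_ss):
            rng = np.random.default_rng(ss)
            train = build_training_design(
                net,
                cfg,
                fold_assignment,
                fold,
                rng,
                cache=cache,
                providers=ensemble_providers,
                target=target,
                mask_tag=repeat,
            )
            test = build_test_design(
                net,
                cfg,
                fold_assignment,
                fold,
                rng,
                cache=cache,
                providers=ensemble_providers,
                target=target,
                mask_tag=repeat,
            )
            clf = train_stacker(train, cfg, rng)
            cache.evict_masked()
            scores = clf.predict_proba(test.X)[:, list(clf.classes_).index(1)]
            aucs.append(auc(scores, test.y))
            _, ap = precision_recall(scores, test.y)
            aps.append(ap)
            importance_rows.append(clf.feature_importances_)
            score_frames.append(
                pd.DataFrame(
                    {
                        "i": test.dyads[:, 0],
                        "j": test.dyads[:, 1],
                        "score": scores,
                        "label": test.y,
                        "fold": fold,
                        "repeat": repeat,
                    }
                )
            )

    columns = _stacked_columns(cfg, ensemble_providers)
    gini = np.mean(importance_rows, axis=0)
    importances = pd.DataFrame(
        {
            "column": columns,
            "feature": [c.split("@")[0] for c in columns],
            "layer_offset": [
                c.split("@")[1] if "@" in c else "" for c in columns
            ],
            "gini": gini,
        }
    )
    return StackingResult(
        mean_auc=float(np.mean(aucs)),
        aucs=aucs,
        mean_ap=float(np.mean(aps)),
        aps=aps,
        importances=importances,
        scores=pd.concat(score_frames, ignore_index=True),
        config=cfg,
    )
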