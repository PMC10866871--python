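"""Interpretable comparators: temporal common neighbors and time-series
feature forecasting.

*Temporal common neighbors* pools ``q`` layers by intersection: node w is a
temporal common neighbor of the dyad (i, j) if w is adjacent to both i and
j in every one of the q layers preceding the target.  The score is the
count of such w.

The *time-series* baseline forecasts each of the 41 per-layer features one
step ahead from its own history (default: an AR(1) conditional mean fitted
by least squares, with a mean fallback for degenerate series) and trains
the same random-forest classifier on forecast vectors instead of stacked
observed vectors.  Both baselines also plug into the stacker as ensemble
score providers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .feature_bank import FEATURE_NAMES, LayerFeatures
from .sequential_stacking import (
    PARTIALLY_OBSERVED,
    FeatureCache,
    StackingConfig,
    LabeledDesign,
    _feature_selector,
    mask_to_observed,
    partition_dyads,
    sample_balanced_dyads,
    train_stacker,
)
from .temporal_graph import TemporalNetwork, intersection_graph

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureHistory",
    "temporal_common_neighbors",
    "temporal_common_neighbors_matrix",
    "build_feature_history",
    "forecast_features",
    "timeseries_scores",
    "run_timeseries_baseline",
    "timeseries_provider",
    "tcn_provider",
]


# -- temporal common neighbors ---------------------------------------------


def temporal_common_neighbors_matrix(
    net: TemporalNetwork, target: int, q: int
) -> np.ndarray:
    """n x n matrix of temporal common-neighbor counts for predicting
    edges in layer ``target`` from the ``q`` layers before it."""
    if target < q:
        raise IndexError(f"target {target} needs q={q} preceding layers")
    inter = intersection_graph(net, target - q, q)
    A = np.zeros((net.n, net.n))
    for u, v in inter.edges():
        A[u, v] = A[v, u] = 1.0
    return A @ A


def temporal_common_neighbors(
    net: TemporalNetwork, target: int, q: int, dyads
) -> np.ndarray:
    """Temporal common-neighbor score for each dyad."""
    dy = np.asarray(dyads, dtype=np.int64).reshape(-1, 2)
    cn = temporal_common_neighbors_matrix(net, target, q)
    return cn[dy[:, 0], dy[:, 1]]


def tcn_provider(net, cfg, dyads, setting, layer) -> np.ndarray:
    """Ensemble provider wrapping temporal common neighbors."""
    return temporal_common_neighbors(net, layer, cfg.q, dyads)


# -- feature forecasting ----------------------------------------------------


@dataclass
class FeatureHistory:
    """Per-dyad, per-feature time series over the layers before a label
    layer: ``values[d, f, s]`` is feature f of dyad d on the s-th history
    layer (oldest first)."""

    dyads: np.ndarray  # (n_dyads, 2)
    values: np.ndarray  # (n_dyads, n_features, horizon)
    feature_names: list[str]
    layers: list[int]

    def __post_init__(self) -> None:
        if self.values.shape != (
            self.dyads.shape[0],
            len(self.feature_names),
            len(self.layers),
        ):
            raise ValueError("history shape inconsistent with dyads/features/layers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature history contains non-finite entries")


def build_feature_history(
    net: TemporalNetwork,
    dyads,
    layers: list[int],
    cfg: StackingConfig | None = None,
    cache: FeatureCache | None = None,
) -> FeatureHistory:
    """Evaluate the feature bank on each history layer for the dyads."""
    cfg = cfg or StackingConfig()
    cache = cache or FeatureCache(cfg)
    sel = _feature_selector(cfg)
    dy = np.asarray(dyads, dtype=np.int64).reshape(-1, 2)
    slices = []
    for t in layers:
        lf = cache.get(("layer", t), net.layer(t))
        slices.append(lf.block(dy).values[:, sel])
    values = np.stack(slices, axis=2) if slices else np.empty((dy.shape[0], len(sel), 0))
    return FeatureHistory(
        dyads=dy,
        values=values,
        feature_names=cfg.feature_names,
        layers=list(layers),
    )


def _ar1_forecast(series: np.ndarray) -> np.ndarray:
    """Vectorized one-step AR(1) conditional mean, least-squares fitted.

    ``series`` is (N, horizon).  Regressing y_t on y_{t-1} with intercept
    gives phi and c; the forecast is ``c + phi * y_last``.  Rows with a
    (numerically) constant regressor fall back to the series mean.
    """
    x = series[:, :-1]
    y = series[:, 1:]
    xm = x.mean(axis=1)
    ym = y.mean(axis=1)
    xc = x - xm[:, None]
    cov = (xc * (y - ym[:, None])).mean(axis=1)
    var = (xc * xc).mean(axis=1)
    ok = var > 1e-12
    phi = np.where(ok, cov / np.where(ok, var, 1.0), 0.0)
    intercept = ym - phi * xm
    forecast = intercept + phi * series[:, -1]
    return np.where(ok, forecast, series.mean(axis=1))


def forecast_features(
    history: FeatureHistory, order: tuple[int, int, int] = (1, 0, 0)
) -> np.ndarray:
    """One-step-ahead forecast of every (dyad, feature) series.

    Fast closed forms are used for the common orders — (1, 0, 0) is the
    least-squares AR(1) conditional mean, (0, 1, 0) a random walk with
    drift (last value plus mean difference) — and constant series forecast
    their constant.  Other orders go through statsmodels ARIMA per series,
    falling back to the series mean on any fit failure.
    """
    n_dyads, n_feat, horizon = history.values.shape
    if horizon < 3:
        raise ValueError(f"need at least 3 observations per series, got {horizon}")
    flat = history.values.reshape(n_dyads * n_feat, horizon)
    const = np.ptp(flat, axis=1) == 0.0

    if order == (1, 0, 0):
        out = _ar1_forecast(flat)
    elif order == (0, 1, 0):
        out = flat[:, -1] + np.diff(flat, axis=1).mean(axis=1)
    else:
        out = _general_arima(flat, const, order)
    out = np.where(const, flat[:, -1], out)
    return out.reshape(n_dyads, n_feat)


def _general_arima(
    flat: np.ndarray, const: np.ndarray, order: tuple[int, int, int]
) -> np.ndarray:
    from statsmodels.tsa.arima.model import ARIMA

    out = np.empty(flat.shape[0])
    failures = 0
    for idx in range(flat.shape[0]):
        if const[idx]:
            out[idx] = flat[idx, -1]
            continue
        try:
            fit = ARIMA(flat[idx], order=order).fit()
            value = float(fit.forecast(1)[0])
            if not np.isfinite(value):
                raise ValueError("non-finite forecast")
            out[idx] = value
        except Exception:
            failures += 1
            out[idx] = flat[idx].mean()
    if failures:
        logger.warning(
            "ARIMA%s failed on %d/%d series; used the series mean",
            order,
            failures,
            flat.shape[0],
        )
    return out


# -- supervised time-series predictor ---------------------------------------


def _history_layers(target: int, u: int) -> list[int]:
    """The up-to-u layers preceding a label layer (at least 3 required)."""
    start = max(0, target - u)
    layers = list(range(start, target))
    if len(layers) < 3:
        raise ValueError(
            f"label layer {target} has only {len(layers)} preceding layers; "
            "need at least 3 for forecasting"
        )
    return layers


def _forecast_design(
    net: TemporalNetwork,
    cfg: StackingConfig,
    label_layers: list[int],
    allowed_masks: list[np.ndarray],
    rng: np.random.Generator,
    cache: FeatureCache,
    order: tuple[int, int, int],
    masked_blocks: list | None = None,
) -> LabeledDesign:
    xs, ys, ds, gs = [], [], [], []
    for gid, (t, allowed) in enumerate(zip(label_layers, allowed_masks)):
        dyads, labels = sample_balanced_dyads(net.layer(t), allowed, cfg.n_pos, rng)
        history = build_feature_history(
            net, dyads, _history_layers(t, cfg.u), cfg, cache
        )
        X = forecast_features(history, order=order)
        if masked_blocks is not None:
            key, g_obs = masked_blocks[gid]
            sel = _feature_selector(cfg)
            X = np.hstack([X, cache.get(key, g_obs).block(dyads).values[:, sel]])
        xs.append(X)
        ys.append(labels)
        ds.append(dyads)
        gs.append(np.full(labels.size, gid, dtype=np.int64))
    columns = [f"{name}@forecast" for name in cfg.feature_names]
    if masked_blocks is not None:
        columns += [f"{name}@t-0" for name in cfg.feature_names]
    return LabeledDesign(
        X=np.vstack(xs),
        y=np.concatenate(ys),
        dyads=np.vstack(ds),
        group_id=np.concatenate(gs),
        columns=columns,
    )


def timeseries_scores(
    net: TemporalNetwork,
    cfg: StackingConfig,
    fold_assignment: np.ndarray,
    test_fold: int,
    rng: np.random.Generator,
    cache: FeatureCache | None = None,
    order: tuple[int, int, int] = (1, 0, 0),
    target: int | None = None,
    mask_tag=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One cross-validation run of the supervised time-series predictor.

    Trains the random forest on per-feature forecasts for the training
    label layers and scores a balanced test sample of target-layer dyads
    from the test fold.  In the partially-observed setting, the observed
    (training-fold-masked) target features are appended to each forecast
    vector.  Returns ``(dyads, labels, scores)``.
    """
    target = net.L if target is None else target
    cache = cache or FeatureCache(cfg)
    training_mask = fold_assignment != test_fold
    label_layers = list(range(target - cfg.u + cfg.q, target))
    allowed = [training_mask] * len(label_layers)
    masked_train = None
    if cfg.setting == PARTIALLY_OBSERVED:
        label_layers = label_layers + [target]
        allowed = allowed + [training_mask]
        masked_train = [
            (("masked", t, test_fold, mask_tag), mask_to_observed(net.layer(t), training_mask))
            for t in label_layers
        ]
    train = _forecast_design(
        net, cfg, label_layers, allowed, rng, cache, order, masked_train
    )

    dyads, labels = sample_balanced_dyads(
        net.layer(target), ~training_mask, cfg.n_pos, rng
    )
    history = build_feature_history(
        net, dyads, _history_layers(target, cfg.u), cfg, cache
    )
    X_test = forecast_features(history, order=order)
    if cfg.setting == PARTIALLY_OBSERVED:
        key = ("masked", target, test_fold, mask_tag)
        g_obs = mask_to_observed(net.layer(target), training_mask)
        sel = _feature_selector(cfg)
        X_test = np.hstack(
            [X_test, cache.get(key, g_obs).block(dyads).values[:, sel]]
        )

    clf = train_stacker(train, cfg, rng)
    scores = clf.predict_proba(X_test)[:, list(clf.classes_).index(1)]
    return dyads, labels, scores


def run_timeseries_baseline(
    net: TemporalNetwork,
    cfg: StackingConfig,
    repeats: int = 10,
    order: tuple[int, int, int] = (1, 0, 0),
    target: int | None = None,
) -> dict:
    """Cross-validated AUC of the time-series predictor (same repeat/fold
    protocol as the stacker).  Returns ``{"mean_auc", "aucs"}``."""
    from .evaluation import auc

    target = net.L if target is None else target
    cache = FeatureCache(cfg)
    aucs = []
    root = np.random.SeedSequence(cfg.seed)
    for repeat, repeat_ss in enumerate(root.spawn(repeats)):
        part_ss, *fold_ss = repeat_ss.spawn(cfg.n_folds + 1)
        fold_assignment = partition_dyads(
            net.layer(target), cfg.n_folds, int(part_ss.generate_state(1)[0] % 2**31)
        )
        for fold, ss in enumerate(fold_ss):
            rng = np.random.default_rng(ss)
            _, labels, scores = timeseries_scores(
                net,
                cfg,
                fold_assignment,
                fold,
                rng,
                cache=cache,
                order=order,
                target=target,
                mask_tag=repeat,
            )
            cache.evict_masked()
            aucs.append(auc(scores, labels))
    return {"mean_auc": float(np.mean(aucs)), "aucs": aucs}


def timeseries_provider(order: tuple[int, int, int] = (1, 0, 0)):
    """Build an ensemble provider from the time-series predictor.

    The provider, called for dyads at a label layer t, trains the forecast
    classifier on balanced samples of the layers between t - (u - q) and
    t - 1 (forecast from each one's own history) and scores the requested
    dyads with forecasts from the layers before t.  Only layers strictly
    before t are touched, so no target-layer structure leaks.
    """

    def _provider(net, cfg, dyads, setting, layer) -> np.ndarray:
        cache = FeatureCache(cfg)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, layer, 7_919]).generate_state(1)
        )
        label_layers = list(range(layer - (cfg.u - cfg.q), layer))
        everything = np.ones(net.n * (net.n - 1) // 2, dtype=bool)
        train = _forecast_design(
            net,
            cfg,
            label_layers,
            [everything] * len(label_layers),
            rng,
            cache,
            order,
        )
        dy = np.asarray(dyads, dtype=np.int64).reshape(-1, 2)
        history = build_feature_history(
            net, dy, _history_layers(layer, cfg.u), cfg, cache
        )
        X = forecast_features(history, order=order)
        clf = train_stacker(train, cfg, rng)
        return clf.predict_proba(X)[:, list(clf.classes_).index(1)]

    _provider.__name__ = f"timeseries{order}"
    return _provider
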