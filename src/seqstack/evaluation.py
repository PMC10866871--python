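"""Metrics, importance aggregation and the synthetic benchmark runner.

AUC here is the probability that a uniformly random true edge receives a
higher score than a uniformly random non-edge, with tied scores counting
one half — computed rank-based so that it matches the pairwise definition
exactly.  Average precision is the area under the step-wise
precision-recall curve with tied scores grouped.

The benchmark runner reproduces the synthetic-study layout: for grid
points of either temporal SBM variant it measures the cross-validated AUC
of the sequential stacker and the interpretable baselines next to the
empirical and exact oracle AUC, emitting one tidy row per
(grid point, setting, method).
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve

from . import tsbm as tsbm_mod
from .sequential_stacking import (
    COMPLETELY_UNOBSERVED,
    StackingConfig,
    all_dyads,
    dyad_index,
    partition_dyads,
    run_sequential_stacking,
    sample_balanced_dyads,
)

logger = logging.getLogger(__name__)

__all__ = [
    "auc",
    "precision_recall",
    "aggregate_importances",
    "evaluate_fixed_scores",
    "run_synthetic_benchmark",
]


class MetricError(ValueError):
    """A metric was requested on a degenerate (single-class) input."""


def auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    Equivalent to the fraction of (positive, negative) pairs where the
    positive outranks the negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks give the half-credit for ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def precision_recall(scores, labels) -> tuple[pd.DataFrame, float]:
    """Step-wise precision-recall curve and average precision."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("precision-recall needs both classes present")
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    ap = float(average_precision_score(labels, scores))
    curve = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "threshold": np.append(thresholds, np.nan),
        }
    )
    return curve, ap


def aggregate_importances(clf, column_names: Sequence[str]) -> pd.DataFrame:
    """Sum Gini importances over the layer-offset copies of each base feature.

    ``column_names`` follow the stacked convention ``<feature>@<offset>``
    (provider columns ``ens:<name>`` pass through unchanged).  Returns a
    table with one row per base feature, sorted descending.
    """
    if not hasattr(clf, "feature_importances_"):
        raise ValueError("classifier is not a fitted tree ensemble")
    imp = np.asarray(clf.feature_importances_, dtype=np.float64)
    if imp.size != len(column_names):
        raise ValueError("column names do not match importance vector length")
    per_column = pd.DataFrame(
        {
            "column": list(column_names),
            "feature": [c.split("@")[0] for c in column_names],
            "gini": imp,
        }
    )
    per_feature = (
        per_column.groupby("feature", as_index=False)["gini"]
        .sum()
        .sort_values("gini", ascending=False, ignore_index=True)
    )
    return per_feature


def top_importances(per_feature: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k most important base features."""
    return per_feature.nlargest(k, "gini").reset_index(drop=True)


def evaluate_fixed_scores(
    net,
    score_matrix: np.ndarray,
    cfg: StackingConfig,
    repeats: int = 10,
    target: int | None = None,
) -> dict:
    """Cross-validated AUC of a fixed per-dyad score matrix (oracle, TCN, or
    any externally computed scorer) under the same balanced fold-sampling
    protocol as the stacker."""
    target = net.L if target is None else target
    dyads = all_dyads(net.n)
    flat = score_matrix[dyads[:, 0], dyads[:, 1]]
    aucs = []
    root = np.random.SeedSequence(cfg.seed)
    for repeat_ss in root.spawn(repeats):
        part_ss, *fold_ss = repeat_ss.spawn(cfg.n_folds + 1)
        assignment = partition_dyads(
            net.layer(target), cfg.n_folds, int(part_ss.generate_state(1)[0] % 2**31)
        )
        for fold, ss in enumerate(fold_ss):
            rng = np.random.default_rng(ss)
            sampled, labels = sample_balanced_dyads(
                net.layer(target), assignment == fold, cfg.n_pos, rng
            )
            idx = dyad_index(net.n, sampled[:, 0], sampled[:, 1])
            aucs.append(auc(flat[idx], labels))
    return {"mean_auc": float(np.mean(aucs)), "aucs": aucs}


def run_synthetic_benchmark(
    variant: str,
    grid: Sequence | None = None,
    settings: Sequence[str] = (COMPLETELY_UNOBSERVED,),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    methods: Sequence[str] = ("stacking", "tcn", "oracle"),
    scale: dict | None = None,
) -> pd.DataFrame:
    """Run the synthetic benchmark over a T-SBM parameter grid.

    Parameters
    ----------
    variant
        ``"community_label"`` or ``"edge_correlated"``.
    grid
        :class:`~seqstack.tsbm.TSBMParams` list; defaults to the full
        45-point grid of the variant.
    settings
        Prediction settings to evaluate.
    seeds
        One network realization (and evaluation stream) per seed.
    methods
        Any of ``stacking`` (Top-Sequential-Stacking), ``tcn``,
        ``timeseries`` and ``oracle`` (empirical oracle AUC).
    scale
        Overrides for desk-scale runs, e.g. ``{"n": 100, "n_pos": 1000,
        "repeats": 5, "n_folds": 5, "classifier_params": {...}}``.
        Defaults keep the grid's own sizes with the standard protocol.

    Returns a tidy frame (variant, p, mu, k, setting, method, seed,
    mean_auc, sd, expected_oracle_auc) with one row per combination;
    failures are logged and recorded with NaN AUC, and the run continues.
    """
    from .baselines import run_timeseries_baseline, temporal_common_neighbors_matrix

    scale = dict(scale or {})
    repeats = scale.pop("repeats", 10)
    n_override = scale.pop("n", None)
    cfg_overrides = scale  # remaining keys feed StackingConfig

    if grid is None:
        grid = tsbm_mod.parameter_grid(variant)

    rows = []
    for params in grid:
        if n_override is not None:
            params = replace(params, n=n_override, theta=None)
        for seed in seeds:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, abs(hash((params.p, params.mu, params.k))) % 2**31])
            )
            net, labels, used = tsbm_mod.generate_tsbm(params, rng)
            if params.variant == "community_label":
                oracle = tsbm_mod.oracle_scores(used, labels[net.L])
            else:
                prev = np.zeros((net.n, net.n), dtype=np.int8)
                for u, v in net.layer(net.L - 1).edges():
                    prev[u, v] = prev[v, u] = 1
                oracle = tsbm_mod.oracle_scores(used, labels, prev)
            dyads = all_dyads(net.n)
            exp_auc = tsbm_mod.expected_oracle_auc(oracle.dyad_probs(dyads))

            for setting in settings:
                cfg = StackingConfig(seed=seed, setting=setting, **cfg_overrides)
                for method in methods:
                    t0 = time.monotonic()
                    try:
                        if method == "stacking":
                            res = run_sequential_stacking(net, cfg, repeats=repeats)
                            mean_auc, aucs = res.mean_auc, res.aucs
                        elif method == "tcn":
                            cn = temporal_common_neighbors_matrix(net, net.L, cfg.q)
                            out = evaluate_fixed_scores(net, cn, cfg, repeats=repeats)
                            mean_auc, aucs = out["mean_auc"], out["aucs"]
                        elif method == "timeseries":
                            out = run_timeseries_baseline(net, cfg, repeats=repeats)
                            mean_auc, aucs = out["mean_auc"], out["aucs"]
                        elif method == "oracle":
                            out = evaluate_fixed_scores(
                                net, oracle.probs, cfg, repeats=repeats
                            )
                            mean_auc, aucs = out["mean_auc"], out["aucs"]
                        else:
                            raise ValueError(f"unknown method {method!r}")
                        sd = float(np.std(aucs))
                    except Exception:
                        logger.exception(
                            "benchmark point failed: %s %s %s seed=%d",
                            params,
                            setting,
                            method,
                            seed,
                        )
                        mean_auc, sd = float("nan"), float("nan")
                    logger.info(
                        "benchmark %s p=%.2f mu=%.2f k=%d %s %s seed=%d: "
                        "auc=%.4f (%.1fs)",
                        variant,
                        params.p,
                        params.mu,
                        params.k,
                        setting,
                        method,
                        seed,
                        mean_auc,
                        time.monotonic() - t0,
                    )
                    rows.append(
                        {
                            "variant": variant,
                            "p": params.p,
                            "mu": params.mu,
                            "k": params.k,
                            "n": params.n,
                            "setting": setting,
                            "method": method,
                            "seed": seed,
                            "mean_auc": mean_auc,
                            "sd": sd,
                            "expected_oracle_auc": exp_auc,
                        }
                    )
    return pd.DataFrame(rows)
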