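import networkx as nx
import numpy as np
import pytest

from seqstack.feature_bank import FEATURE_NAMES
from seqstack.sequential_stacking import (
    COMPLETELY_UNOBSERVED,
    PARTIALLY_OBSERVED,
    LabeledDesign,
    ProviderError,
    StackingConfig,
    all_dyads,
    build_test_design,
    build_training_design,
    dyad_index,
    edge_mask,
    mask_to_observed,
    partition_dyads,
    run_sequential_stacking,
    sample_balanced_dyads,
    train_stacker,
)
from seqstack.temporal_graph import TemporalNetwork
from seqstack.tsbm import block_probability_matrix

FAST_RF = {"n_estimators": 50}


def tiny_cfg(**kw):
    defaults = dict(n_pos=100, seed=0, classifier_params=FAST_RF)
    defaults.update(kw)
    return StackingConfig(**defaults)


class TestDyadIndexing:
    def test_roundtrip(self):
        n = 37
        dy = all_dyads(n)
        assert dy.shape == (n * (n - 1) // 2, 2)
        idx = dyad_index(n, dy[:, 0], dy[:, 1])
        np.testing.assert_array_equal(idx, np.arange(dy.shape[0]))

    def test_edge_mask(self):
        g = nx.path_graph(4)
        mask = edge_mask(g, 4)
        dy = all_dyads(4)
        marked = {tuple(d) for d in dy[mask]}
        assert marked == {(0, 1), (1, 2), (2, 3)}


class TestPartition:
    def test_200_node_fold_sizes(self):
        g = nx.gnp_random_graph(200, 0.05, seed=1)
        folds = partition_dyads(g, 5, seed=0)
        assert folds.size == 19_900
        counts = np.bincount(folds, minlength=5)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 19_900

    def test_exact_edge_stratification(self):
        g = nx.Graph()
        g.add_nodes_from(range(30))
        g.add_edges_from((i, i + 1) for i in range(10))  # 10 edges
        folds = partition_dyads(g, 5, seed=3)
        is_edge = edge_mask(g, 30)
        per_fold_edges = np.bincount(folds[is_edge], minlength=5)
        np.testing.assert_array_equal(per_fold_edges, [2, 2, 2, 2, 2])

    def test_nonedge_stratification(self):
        g = nx.gnp_random_graph(40, 0.2, seed=4)
        folds = partition_dyads(g, 5, seed=9)
        for mask in (edge_mask(g, 40), ~edge_mask(g, 40)):
            counts = np.bincount(folds[mask], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_seed_determinism(self):
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        a = partition_dyads(g, 5, seed=11)
        b = partition_dyads(g, 5, seed=11)
        c = partition_dyads(g, 5, seed=12)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.array_equal(
            np.bincount(a, minlength=5), np.bincount(c, minlength=5)
        )


class TestBalancedSampling:
    def test_forced_duplication(self, rng):
        g = nx.Graph()
        g.add_nodes_from(range(2))
        g.add_edge(0, 1)
        # universe of 3 nodes: dyads (0,1) edge, (0,2), (1,2) non-edges
        g.add_node(2)
        allowed = np.array([True, True, False])
        dyads, labels = sample_balanced_dyads(g, allowed, 5, rng)
        assert dyads.shape == (10, 2)
        assert labels.sum() == 5
        assert all(tuple(d) == (0, 1) for d in dyads[:5])
        assert all(tuple(d) == (0, 2) for d in dyads[5:])

    def test_class_counts_always_balanced(self, rng):
        g = nx.gnp_random_graph(20, 0.3, seed=6)
        dyads, labels = sample_balanced_dyads(
            g, np.ones(190, dtype=bool), 37, rng
        )
        assert (labels == 1).sum() == 37 and (labels == 0).sum() == 37

    def test_uniformity_over_edges(self, rng):
        g = nx.Graph()
        g.add_nodes_from(range(10))
        edges = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]
        g.add_edges_from(edges)
        dyads, labels = sample_balanced_dyads(
            g, np.ones(45, dtype=bool), 50_000, rng
        )
        pos = dyads[labels == 1]
        idx = dyad_index(10, pos[:, 0], pos[:, 1])
        freq = np.bincount(idx, minlength=45) / 50_000
        for i, j in edges:
            assert abs(freq[dyad_index(10, np.int64(i), np.int64(j))] - 0.2) < 0.01

    def test_error_when_class_missing(self, rng):
        g = nx.empty_graph(5)
        with pytest.raises(ValueError, match="edge"):
            sample_balanced_dyads(g, np.ones(10, dtype=bool), 3, rng)


class TestMasking:
    def test_full_mask_is_identity(self):
        g = nx.gnp_random_graph(15, 0.3, seed=7)
        obs = mask_to_observed(g, np.ones(105, dtype=bool))
        assert set(obs.edges()) == set(g.edges())

    def test_empty_mask_removes_everything(self):
        g = nx.gnp_random_graph(15, 0.3, seed=7)
        obs = mask_to_observed(g, np.zeros(105, dtype=bool))
        assert obs.number_of_edges() == 0
        assert obs.number_of_nodes() == 15

    def test_matches_set_filter(self, rng):
        g = nx.gnp_random_graph(20, 0.3, seed=8)
        keep = rng.random(190) < 0.5
        obs = mask_to_observed(g, keep)
        dy = all_dyads(20)
        expected = {
            (min(u, v), max(u, v))
            for u, v in g.edges()
            if keep[dyad_index(20, min(u, v), max(u, v))]
        }
        assert {tuple(sorted(e)) for e in obs.edges()} == expected


@pytest.fixture(scope="module")
def design_net():
    layers = [nx.gnp_random_graph(40, 0.15, seed=100 + t) for t in range(10)]
    return TemporalNetwork(n=40, layers=layers)


class TestDesigns:
    def test_unobserved_group_and_row_counts(self, design_net):
        cfg = tiny_cfg(u=6, q=3)
        folds = partition_dyads(design_net.layer(9), 5, seed=0)
        design = build_training_design(
            design_net, cfg, folds, 0, np.random.default_rng(0)
        )
        assert len(np.unique(design.group_id)) == 3  # u - q groups
        assert design.X.shape == (6 * cfg.n_pos, 123)  # 41q columns

    def test_partial_group_and_column_counts(self, design_net):
        cfg = tiny_cfg(u=6, q=3, setting=PARTIALLY_OBSERVED)
        folds = partition_dyads(design_net.layer(9), 5, seed=0)
        design = build_training_design(
            design_net, cfg, folds, 0, np.random.default_rng(0)
        )
        assert len(np.unique(design.group_id)) == 4  # u - q + 1 groups
        assert design.X.shape == (8 * cfg.n_pos, 164)  # 41(q+1) columns

    def test_minimum_history_single_group(self, design_net):
        cfg = tiny_cfg(u=4, q=3)
        folds = partition_dyads(design_net.layer(9), 5, seed=0)
        design = build_training_design(
            design_net, cfg, folds, 0, np.random.default_rng(0)
        )
        assert len(np.unique(design.group_id)) == 1

    def test_test_design_rows_and_columns(self, design_net):
        cfg = tiny_cfg(u=6, q=3)
        folds = partition_dyads(design_net.layer(9), 5, seed=0)
        design = build_test_design(
            design_net, cfg, folds, 0, np.random.default_rng(0)
        )
        assert design.X.shape == (2 * cfg.n_pos, 123)
        assert (design.y == 1).sum() == (design.y == 0).sum() == cfg.n_pos

    def test_test_rows_come_from_test_fold(self, design_net):
        cfg = tiny_cfg(u=6, q=3)
        folds = partition_dyads(design_net.layer(9), 5, seed=0)
        design = build_test_design(
            design_net, cfg, folds, 2, np.random.default_rng(0)
        )
        idx = dyad_index(40, design.dyads[:, 0], design.dyads[:, 1])
        assert np.all(folds[idx] == 2)

    def test_training_rows_avoid_test_fold(self, design_net):
        cfg = tiny_cfg(u=6, q=3, setting=PARTIALLY_OBSERVED)
        folds = partition_dyads(design_net.layer(9), 5, seed=0)
        design = build_training_design(
            design_net, cfg, folds, 2, np.random.default_rng(0)
        )
        idx = dyad_index(40, design.dyads[:, 0], design.dyads[:, 1])
        assert np.all(folds[idx] != 2)

    @pytest.mark.parametrize("setting", [COMPLETELY_UNOBSERVED, PARTIALLY_OBSERVED])
    def test_no_leakage_from_test_fold_edges(self, design_net, setting):
        """Deleting the target layer's test-fold edges changes nothing in the
        training design, and no test feature value in either setting."""
        cfg = tiny_cfg(u=6, q=3, setting=setting)
        folds = partition_dyads(design_net.layer(9), 5, seed=0)
        test_fold = 1

        pruned_layers = [g.copy() for g in design_net.layers]
        target = pruned_layers[9]
        for u, v in list(target.edges()):
            a, b = min(u, v), max(u, v)
            if folds[dyad_index(40, np.int64(a), np.int64(b))] == test_fold:
                target.remove_edge(u, v)
        pruned = TemporalNetwork(n=40, layers=pruned_layers)

        train_a = build_training_design(
            design_net, cfg, folds, test_fold, np.random.default_rng(5)
        )
        train_b = build_training_design(
            pruned, cfg, folds, test_fold, np.random.default_rng(5)
        )
        np.testing.assert_array_equal(train_a.X, train_b.X)
        np.testing.assert_array_equal(train_a.y, train_b.y)
        np.testing.assert_array_equal(train_a.dyads, train_b.dyads)

        # identical dyads on both networks must get identical test features
        test_a = build_test_design(
            design_net, cfg, folds, test_fold, np.random.default_rng(6)
        )
        from seqstack.sequential_stacking import FeatureCache, _stack_rows

        masked = None
        if setting == PARTIALLY_OBSERVED:
            masked = (
                ("masked", 9, test_fold, "chk"),
                mask_to_observed(pruned.layer(9), folds != test_fold),
            )
        X_b = _stack_rows(
            pruned, cfg, FeatureCache(cfg), test_a.dyads, 9, masked, None
        )
        np.testing.assert_array_equal(test_a.X, X_b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StackingConfig(u=3, q=3)
        with pytest.raises(ValueError):
            StackingConfig(n_folds=1)
        with pytest.raises(ValueError):
            StackingConfig(features=["not-a-feature"])


class TestTrainStacker:
    def _noise_design(self, rng, rows=400, cols=10):
        X = rng.normal(size=(rows, cols))
        y = np.concatenate([np.ones(rows // 2, int), np.zeros(rows // 2, int)])
        return LabeledDesign(
            X=X,
            y=y,
            dyads=np.zeros((rows, 2), dtype=np.int64),
            group_id=np.zeros(rows, dtype=np.int64),
            columns=[f"f{i}@t-1" for i in range(cols)],
        )

    def test_separable_column_dominates(self, rng):
        design = self._noise_design(rng)
        design.X[:, 4] = design.y + 0.01 * rng.normal(size=design.y.size)
        clf = train_stacker(design, tiny_cfg(), rng)
        assert clf.score(design.X, design.y) == 1.0
        assert np.argmax(clf.feature_importances_) == 4

    def test_importances_sum_to_one(self, rng):
        design = self._noise_design(rng)
        clf = train_stacker(design, tiny_cfg(), rng)
        assert abs(clf.feature_importances_.sum() - 1.0) < 1e-9

    def test_single_class_rejected(self, rng):
        design = self._noise_design(rng)
        design.y[:] = 1
        with pytest.raises(ValueError, match="both classes"):
            train_stacker(design, tiny_cfg(), rng)

    def test_pure_noise_has_no_skill(self):
        """Out-of-sample AUC on pure-noise features stays at chance."""
        from seqstack.evaluation import auc

        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            design = self._noise_design(rng, rows=300)
            clf = train_stacker(design, tiny_cfg(), rng)
            fresh = self._noise_design(rng, rows=300)
            scores = clf.predict_proba(fresh.X)[:, 1]
            aucs.append(auc(scores, fresh.y))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_grid_selection_runs(self, rng):
        design = self._noise_design(rng)
        cfg = tiny_cfg(
            classifier_params={
                "n_estimators": 25,
                "grid": [{"min_samples_leaf": 1}, {"min_samples_leaf": 5}],
            }
        )
        clf = train_stacker(design, cfg, rng)
        assert hasattr(clf, "feature_importances_")


class TestPipeline:
    def test_reproducible_and_counts(self, design_net):
        cfg = tiny_cfg(n_pos=50, n_folds=3, classifier_params={"n_estimators": 25})
        a = run_sequential_stacking(design_net, cfg, repeats=2)
        b = run_sequential_stacking(design_net, cfg, repeats=2)
        assert a.aucs == b.aucs
        assert len(a.aucs) == 2 * 3
        assert a.mean_auc == pytest.approx(np.mean(a.aucs))
        assert np.all(a.importances["gini"] >= 0)
        assert set(a.scores.columns) == {"i", "j", "score", "label", "fold", "repeat"}

    def test_zero_providers_is_top_stacking(self, design_net):
        cfg = tiny_cfg(n_pos=50, n_folds=2, classifier_params={"n_estimators": 25})
        a = run_sequential_stacking(design_net, cfg, repeats=1)
        b = run_sequential_stacking(design_net, cfg, ensemble_providers=[], repeats=1)
        assert a.aucs == b.aucs

    def test_provider_column_appended(self, design_net):
        cfg = tiny_cfg(n_pos=50, n_folds=2, classifier_params={"n_estimators": 25})

        def flat_provider(net, cfg_, dyads, setting, layer):
            return np.zeros(len(dyads))

        res = run_sequential_stacking(
            design_net, cfg, ensemble_providers=[flat_provider], repeats=1
        )
        assert "ens:flat_provider" in list(res.importances["column"])
        assert len(res.importances) == 41 * 3 + 1

    def test_bad_provider_reported(self, design_net):
        cfg = tiny_cfg(n_pos=50, n_folds=2, classifier_params={"n_estimators": 25})

        def short_provider(net, cfg_, dyads, setting, layer):
            return np.zeros(3)

        with pytest.raises(ProviderError, match="short_provider"):
            run_sequential_stacking(
                design_net, cfg, ensemble_providers=[short_provider], repeats=1
            )

    def test_oracle_provider_does_not_hurt(self, small_tsbm_net):
        """Appending the generative model's own probabilities as an ensemble
        column keeps performance within noise of Top-Sequential-Stacking."""
        net, labels, params = small_tsbm_net
        base = block_probability_matrix(params, labels)

        def oracle_provider(net_, cfg_, dyads, setting, layer):
            prev = nx.to_numpy_array(net_.layer(layer - 1))
            probs = params.p * prev + (1 - params.p) * base
            dy = np.asarray(dyads).reshape(-1, 2)
            return probs[dy[:, 0], dy[:, 1]]

        cfg = tiny_cfg(n_pos=200, n_folds=3, classifier_params={"n_estimators": 100})
        top = run_sequential_stacking(net, cfg, repeats=2)
        ens = run_sequential_stacking(
            net, cfg, ensemble_providers=[oracle_provider], repeats=2
        )
        assert ens.mean_auc >= top.mean_auc - 0.02

    def test_feature_subset_restricts_columns(self, design_net):
        cfg = tiny_cfg(
            n_pos=50, n_folds=2, features=["CN"], classifier_params={"n_estimators": 25}
        )
        folds = partition_dyads(design_net.layer(9), 2, seed=0)
        design = build_test_design(
            design_net, cfg, folds, 0, np.random.default_rng(0)
        )
        assert design.X.shape[1] == 3
        assert design.columns == ["CN@t-3", "CN@t-2", "CN@t-1"]

    def test_target_needs_enough_history(self, design_net):
        cfg = tiny_cfg(u=6, q=3)
        with pytest.raises(ValueError, match="preceding"):
            run_sequential_stacking(design_net, cfg, target=4)
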