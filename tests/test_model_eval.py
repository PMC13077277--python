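"""The cross-validation framework: folds, scaling, ranking, metrics, sweep."""

import numpy as np
import pandas as pd
import pytest
import sklearn.metrics

from gaitpipe.model_eval import (
    CVPlan,
    EvaluationError,
    RankingSpec,
    SingleClassFoldError,
    aggregate_curves,
    apply_zscale,
    auc_roc,
    balanced_weights,
    compute_metrics,
    fit_predict,
    rank_features,
    results_to_frame,
    run_topk_sweep,
    stratified_folds,
    zscale,
)


class TestStratifiedFolds:
    def test_even_distribution_within_classes(self):
        labels = np.array([1] * 12 + [0] * 8)
        folds = stratified_folds(labels, 5, seed=0)
        for f in range(5):
            assert (folds == f).sum() == 4
            for cls, n_cls in ((1, 12), (0, 8)):
                in_fold = ((folds == f) & (labels == cls)).sum()
                assert np.floor(n_cls / 5) <= in_fold <= np.ceil(n_cls / 5)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            stratified_folds(np.ones(20), 5, seed=0)

    def test_deterministic(self):
        labels = np.array([0, 1] * 15)
        np.testing.assert_array_equal(
            stratified_folds(labels, 5, 7), stratified_folds(labels, 5, 7)
        )


class TestZScale:
    def test_two_point_column(self):
        scaler, scaled = zscale(np.array([[1.0], [3.0]]))
        np.testing.assert_array_equal(scaled.ravel(), [-1.0, 1.0])

    def test_constant_column_maps_to_zero_in_train_and_test(self):
        scaler, scaled = zscale(np.array([[5.0], [5.0], [5.0]]))
        assert np.all(scaled == 0)
        assert np.all(apply_zscale(scaler, np.array([[7.0], [2.0]])) == 0)

    def test_refit_consistency(self, rng):
        X = rng.normal(size=(20, 4))
        scaler, scaled = zscale(X)
        np.testing.assert_array_equal(apply_zscale(scaler, X), scaled)


class TestBalancedWeights:
    def test_formula_7_3(self):
        w = balanced_weights(np.array([1] * 7 + [0] * 3))
        assert w[0] == pytest.approx(10 / 14)
        assert w[-1] == pytest.approx(10 / 6)

    def test_balanced_classes_give_unit_weights(self):
        assert np.all(balanced_weights(np.array([0] * 5 + [1] * 5)) == 1.0)

    def test_weights_sum_to_n(self, rng):
        labels = rng.integers(0, 2, 37)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert balanced_weights(labels).sum() == pytest.approx(37)


class TestRankFeatures:
    def test_informative_feature_ranks_first(self, rng):
        """A label-copy feature beats 49 noise features in >=95/100 runs."""
        hits = 0
        for run in range(100):
            r = np.random.default_rng(run)
            y = r.integers(0, 2, 200)
            X = r.normal(size=(200, 50))
            X[:, 17] = y * 2.0 - 1.0
            names = [f"f{i:02d}" for i in range(50)]
            _, scaled = zscale(X)
            ranking = rank_features(scaled, y, names)
            hits += ranking[0] == "f17"
        assert hits >= 95

    def test_identical_columns_tie_break_lexicographic(self, rng):
        y = rng.integers(0, 2, 60)
        col = rng.normal(size=60)
        X = np.tile(col[:, None], (1, 4))
        names = ["b", "d", "a", "c"]
        _, scaled = zscale(X)
        ranking = rank_features(scaled, y, names)
        assert ranking == sorted(names)

    def test_duplicating_a_column_does_not_promote_unrelated_features(self, rng):
        """Relative order of non-duplicated features survives duplication."""
        for trial in range(50):
            r = np.random.default_rng(trial)
            y = r.integers(0, 2, 80)
            X = r.normal(size=(80, 8)) + y[:, None] * r.uniform(0, 1, 8)
            names = [f"f{i}" for i in range(8)]
            _, scaled = zscale(X)
            base = rank_features(scaled, y, names)
            Xd = np.column_stack([X, X[:, 0]])
            _, scaled_d = zscale(Xd)
            dup = rank_features(scaled_d, y, names + ["f0_copy"])
            base_rest = [n for n in base if n != "f0"]
            dup_rest = [n for n in dup if n not in ("f0", "f0_copy")]
            # ranking among untouched features must not be reshuffled past f0
            assert set(dup_rest) == set(base_rest)


class TestFitPredict:
    def _separable(self):
        X = np.vstack([np.full((20, 2), -2.0), np.full((20, 2), 2.0)])
        y = np.array([0] * 20 + [1] * 20)
        return X, y

    @pytest.mark.parametrize("model", ["enet_lr", "hist_gb"])
    def test_separable_toy_set_auc_1(self, model):
        X, y = self._separable()
        w = balanced_weights(y)
        probs = fit_predict(model, X, y, w, X)
        assert auc_roc(y, probs) == 1.0

    @pytest.mark.parametrize("model", ["enet_lr", "hist_gb"])
    def test_permuted_labels_near_chance(self, model, rng):
        X = rng.normal(size=(150, 5))
        y = rng.integers(0, 2, 150)
        test = rng.normal(size=(50, 5))
        y_test = rng.integers(0, 2, 50)
        probs = fit_predict(model, X, y, balanced_weights(y), test)
        assert 0.3 <= auc_roc(y_test, probs) <= 0.7

    def test_deterministic(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, 60)
        w = balanced_weights(y)
        for model in ("enet_lr", "hist_gb"):
            p1 = fit_predict(model, X, y, w, X, seed=3)
            p2 = fit_predict(model, X, y, w, X, seed=3)
            np.testing.assert_array_equal(p1, p2)

    def test_mismatched_columns_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.array([0, 1] * 10)
        with pytest.raises(EvaluationError):
            fit_predict("enet_lr", X, y, balanced_weights(y), rng.normal(size=(5, 3)))


class TestComputeMetrics:
    def test_perfect_ranking(self):
        m = compute_metrics(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.3, 0.2]))
        assert (m.auc_roc, m.accuracy, m.mcc) == (1.0, 1.0, 1.0)

    def test_interleaved_scores_auc(self):
        m = compute_metrics(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.3, 0.2]))
        assert m.auc_roc == 0.75  # brute force over the 4 pos-neg pairs

    def test_confusion_matrix_formulas(self):
        # TP=3, FP=1, FN=2, TN=4
        y = np.array([1] * 5 + [0] * 5)
        p = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.9, 0.1, 0.1, 0.1, 0.1])
        m = compute_metrics(y, p)
        assert m.mcc == pytest.approx(10 / np.sqrt(600))
        assert m.sensitivity_class1 == pytest.approx(0.6)
        assert m.sensitivity_class0 == pytest.approx(0.8)

    def test_auc_equals_brute_force_pairwise(self, rng):
        """Rank AUC == mean pairwise comparison with tie credit, 500 sets."""
        for _ in range(500):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
            pos, neg = scores[y == 1], scores[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc_roc(y, scores) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_threshold_metrics_match_sklearn(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = rng.uniform(0, 1, 30)
            pred = (p >= 0.5).astype(int)
            m = compute_metrics(y, p)
            assert m.accuracy == pytest.approx(sklearn.metrics.accuracy_score(y, pred))
            assert m.mcc == pytest.approx(sklearn.metrics.matthews_corrcoef(y, pred))
            f1 = sklearn.metrics.f1_score(y, pred, average=None, labels=[0, 1],
                                          zero_division=0.0)
            assert (m.f1_class0, m.f1_class1) == pytest.approx(tuple(f1))
            assert m.auc_roc == pytest.approx(sklearn.metrics.roc_auc_score(y, p))

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        p = rng.uniform(0, 1, 40)
        base = auc_roc(y, p)
        assert auc_roc(y, p**3) == base
        assert auc_roc(y, np.exp(5 * p)) == base

    def test_mcc_label_swap_symmetry(self, rng):
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        p = rng.uniform(0, 1, 40)
        m = compute_metrics(y, p)
        m_swapped = compute_metrics(1 - y, 1 - p + 1e-12)
        assert m_swapped.mcc == pytest.approx(m.mcc)

    def test_single_class_truth_raises(self):
        with pytest.raises(SingleClassFoldError):
            compute_metrics(np.ones(5, dtype=int), np.full(5, 0.5))


class TestSweep:
    def test_counts_and_fold_conservation(self, small_sweep):
        sweep, X, y, plan = small_sweep
        frame = results_to_frame(sweep)
        counts = frame.groupby(["model", "k"]).size()
        assert set(counts) == {plan.n_evaluations}
        # every sample appears in exactly one test fold per repetition
        for rep in range(plan.n_repetitions):
            seen = []
            for r in sweep.results:
                if r.repetition == rep and r.model == "enet_lr" and r.k == 1:
                    seen.extend(r.test_ids)
            assert sorted(seen) == sorted(X.index)

    def test_rerun_is_byte_identical(self, small_sweep):
        sweep, X, y, plan = small_sweep
        again = run_topk_sweep(X, y, [1, 5, 15], plan)
        a, b = results_to_frame(sweep), results_to_frame(again)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_folds_shared_across_k_and_models(self, small_sweep):
        sweep, *_ = small_sweep
        by_cell = {}
        for r in sweep.results:
            key = (r.repetition, r.fold)
            by_cell.setdefault(key, set()).add(r.test_ids)
        assert all(len(v) == 1 for v in by_cell.values())

    def test_leakage_guard(self, small_table):
        """Corrupting a test-fold row changes nothing fitted on its train fold."""
        from gaitpipe.pipeline import outcome_labels, split_feature_table

        table, _ = small_table
        X, _ = split_feature_table(table)
        y = outcome_labels(table, "sex")
        plan = CVPlan(n_folds=5, n_repetitions=1, base_seed=0)
        base = run_topk_sweep(X, y, [5], plan, models=("enet_lr",))

        victim = X.index[0]
        X_mut = X.copy()
        X_mut.loc[victim] = X_mut.loc[victim] * 10 + 7.0
        mutated = run_topk_sweep(X_mut, y, [5], plan, models=("enet_lr",))

        for rb, rm in zip(base.results, mutated.results):
            assert rb.test_ids == rm.test_ids
            if victim in rb.test_ids:
                # same train fold -> same ranking and same model: every other
                # test sample's probability is unchanged
                assert rb.selected_features == rm.selected_features
                keep = [i for i, rid in enumerate(rb.test_ids) if rid != victim]
                np.testing.assert_allclose(
                    rb.test_probabilities[keep], rm.test_probabilities[keep], rtol=1e-12
                )

    def test_k_exceeding_feature_count_rejected(self, small_table):
        from gaitpipe.pipeline import outcome_labels, split_feature_table

        table, _ = small_table
        X, _ = split_feature_table(table)
        y = outcome_labels(table, "sex")
        with pytest.raises(EvaluationError):
            run_topk_sweep(X, y, [X.shape[1] + 1], CVPlan(n_repetitions=1))


class TestAggregateCurves:
    def test_hand_built_aggregation(self):
        rows = []
        for i, auc in enumerate([0.6, 0.8, 0.7, 0.9]):
            rows.append({"model": "enet_lr", "k": 5, "repetition": i, "fold": 0,
                         "auc_roc": auc, "accuracy": 0.5, "mcc": 0.0,
                         "sensitivity_class0": 1.0, "sensitivity_class1": 0.0,
                         "f1_class0": 0.5, "f1_class1": 0.5})
        curves = aggregate_curves(pd.DataFrame(rows))
        row = curves.iloc[0]
        assert row["auc_roc_mean"] == pytest.approx(0.75)
        assert row["auc_roc_sd"] == pytest.approx(np.std([0.6, 0.8, 0.7, 0.9]))
        assert row["accuracy_sd"] == 0.0
        assert row["n_evaluations"] == 4

    def test_curve_rises_from_k1_to_k15_on_synthetic_sex_signal(self, small_sweep):
        sweep, *_ = small_sweep
        curves = aggregate_curves(sweep)
        for model in ("enet_lr", "hist_gb"):
            sub = curves[curves["model"] == model].set_index("k")
            assert sub.loc[15, "auc_roc_mean"] >= sub.loc[1, "auc_roc_mean"]
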