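"""Stratified metrics, subgroup reruns, individual rankings, feature stats."""

import numpy as np
import pandas as pd
import pytest

from gaitpipe.model_eval import CVPlan, results_to_frame, run_topk_sweep
from gaitpipe.pipeline import outcome_labels, split_feature_table
from gaitpipe.sensitivity import (
    StratumSpec,
    feature_distributions,
    pooled_predictions,
    rank_individuals,
    selection_frequency,
    stratum_metrics,
    subgroup_rerun,
)


@pytest.fixture(scope="module")
def preds(small_sweep):
    sweep, X, y, plan = small_sweep
    return pooled_predictions(sweep, "enet_lr", 15), X, y


class TestStratumMetrics:
    def test_duplicate_full_cohort_strata_agree(self, preds):
        p, X, y = preds
        full = pd.Series(True, index=X.index)
        out = stratum_metrics(p, [StratumSpec("a", full), StratumSpec("b", full)])
        a, b = out.iloc[0], out.iloc[1]
        for col in ("auc_roc", "accuracy", "mcc"):
            assert a[col] == b[col]
        assert a["n_samples"] == len(X)

    def test_partition_counts_sum_to_cohort(self, preds):
        p, X, y = preds
        half = pd.Series(np.arange(len(X)) < len(X) // 2, index=X.index)
        out = stratum_metrics(p, [StratumSpec("lo", half), StratumSpec("hi", ~half)])
        assert out["n_samples"].sum() == len(X)

    def test_single_sample_stratum_has_undefined_auc(self, preds):
        p, X, y = preds
        one = pd.Series(False, index=X.index)
        one.iloc[0] = True
        out = stratum_metrics(p, [StratumSpec("one", one)])
        assert np.isnan(out.iloc[0]["auc_roc"])
        assert out.iloc[0]["n_samples"] == 1

    def test_empty_stratum_reported_not_raised(self, preds):
        p, X, y = preds
        none = pd.Series(False, index=X.index)
        out = stratum_metrics(p, [StratumSpec("none", none)])
        assert out.iloc[0]["n_predictions"] == 0


class TestSubgroupRerun:
    def test_full_cohort_subgroup_equals_pooled_run(self, small_sweep):
        sweep, X, y, plan = small_sweep
        rerun = subgroup_rerun(X, y, list(X.index), [1, 5, 15], plan)
        pd.testing.assert_frame_equal(results_to_frame(sweep), results_to_frame(rerun))

    def test_site_subgroups_reach_similar_discrimination(self, small_table):
        """Shared effects, site-specific camera scale: site AUC curves agree.

        Each site's rerun at k=15 must lie within the other's +/-2 SD band.
        """
        from gaitpipe.model_eval import aggregate_curves

        table, _ = small_table
        X, _ = split_feature_table(table)
        y = outcome_labels(table, "sex")
        plan = CVPlan(n_folds=5, n_repetitions=3, base_seed=4)
        bands = {}
        for site in ("thailand", "india"):
            ids = list(table.index[table.site == site])
            out = subgroup_rerun(X, y, ids, [15], plan, models=("enet_lr",))
            row = aggregate_curves(out).iloc[0]
            bands[site] = (row["auc_roc_mean"], row["auc_roc_sd"])
        (m1, s1), (m2, s2) = bands["thailand"], bands["india"]
        assert abs(m1 - m2) <= 2 * max(s1, s2)

    def test_disjoint_subgroups_use_disjoint_samples(self, small_sweep):
        _, X, y, _ = small_sweep
        plan = CVPlan(n_folds=3, n_repetitions=1, base_seed=0)
        ids = list(X.index)
        a = subgroup_rerun(X, y, ids[:30], [3], plan, models=("enet_lr",))
        b = subgroup_rerun(X, y, ids[30:], [3], plan, models=("enet_lr",))
        seen_a = {rid for r in a.results for rid in r.test_ids}
        seen_b = {rid for r in b.results for rid in r.test_ids}
        assert seen_a.isdisjoint(seen_b)
        assert seen_a <= set(ids[:30]) and seen_b <= set(ids[30:])


class TestRankIndividuals:
    def _mock_predictions(self):
        rows = []
        for rep in range(4):
            for i in range(12):
                rid = f"r{i:02d}"
                y = i % 2
                p = 1.0 if i == 0 else 0.2 + 0.05 * i
                if y == 0:
                    p = 1 - p
                rows.append({"recording_id": rid, "repetition": rep,
                             "y_true": y, "probability": p if y == 1 else 1 - (1 - p)})
        return pd.DataFrame(rows)

    def test_always_certain_individual_tops_best_list(self):
        df = self._mock_predictions()
        best, worst = rank_individuals(df, n_top=3)
        assert best[0].recording_id == "r00"
        assert best[0].mean_correct_class_probability == 1.0
        assert best[0].n_predictions == 4

    def test_best_and_worst_disjoint(self, preds):
        p, X, y = preds
        best, worst = rank_individuals(p, n_top=10)
        assert len(best) == len(worst) == 10
        assert {b.recording_id for b in best}.isdisjoint({w.recording_id for w in worst})

    def test_stable_under_row_reordering(self, preds):
        p, X, y = preds
        shuffled = p.sample(frac=1.0, random_state=9).reset_index(drop=True)
        b1, w1 = rank_individuals(p)
        b2, w2 = rank_individuals(shuffled)
        assert [s.recording_id for s in b1] == [s.recording_id for s in b2]
        assert [s.recording_id for s in w1] == [s.recording_id for s in w2]

    def test_loose_clothing_individuals_predicted_worse(self):
        """Heavy lower-body jitter degrades age predictions for those recordings.

        Six recordings (three per age class, so the corruption cannot become
        a class shortcut) are re-rendered with loose-clothing jitter; across
        eight seeded cohorts their mean out-of-fold true-class probability
        falls below the clean recordings', and some land in the worst-10.
        """
        from gaitpipe.pipeline import build_feature_table
        from gaitpipe.synthetic_gait import (
            EffectConfig, NoiseConfig, generate_walk, sample_cohort, sample_subject,
        )

        diffs, hits = [], 0
        for seed in range(80, 88):
            cohort = sample_cohort(50, rng_seed=seed,
                                   noise=NoiseConfig(jitter_sd_px=2.0))
            old = [i for i, (_, m) in enumerate(cohort) if m.age_years >= 65][:3]
            young = [i for i, (_, m) in enumerate(cohort) if m.age_years < 65][:3]
            flag_idx = set(old + young)
            flagged, degraded = [], []
            for i, (seq, meta) in enumerate(cohort):
                if i in flag_idx:
                    subj = sample_subject(meta.sex, meta.age_group, EffectConfig(),
                                          i + 500 + seed)
                    noisy = generate_walk(
                        subj, 4, 30.0,
                        NoiseConfig(jitter_sd_px=8.0, loose_clothing_mode=True),
                        rng_seed=i + 900)
                    degraded.append((noisy, meta))
                    flagged.append(meta.recording_id)
                else:
                    degraded.append((seq, meta))
            table, _ = build_feature_table(degraded)
            X, _ = split_feature_table(table)
            y = outcome_labels(table, "age")
            sweep = run_topk_sweep(X, y, [10],
                                   CVPlan(n_folds=5, n_repetitions=4, base_seed=1),
                                   models=("enet_lr",))
            p = pooled_predictions(sweep, "enet_lr", 10)
            p["pc"] = np.where(p.y_true == 1, p.probability, 1 - p.probability)
            per_id = p.groupby("recording_id")["pc"].mean()
            present = [r for r in flagged if r in per_id.index]
            diffs.append(per_id.drop(present).mean() - per_id.loc[present].mean())
            _, worst = rank_individuals(p, n_top=10)
            hits += len({w.recording_id for w in worst} & set(flagged))
        assert np.mean(diffs) > 0
        assert hits >= 6


class TestSelectionFrequency:
    def test_exhaustive_selection_gives_unit_frequency(self, small_table):
        table, _ = small_table
        X, _ = split_feature_table(table)
        X10 = X.iloc[:, :10]
        y = outcome_labels(table, "sex")
        sweep = run_topk_sweep(X10, y, [10], CVPlan(n_folds=5, n_repetitions=1),
                               models=("enet_lr",))
        freq = selection_frequency(sweep, "enet_lr", 10)
        assert np.all(freq.to_numpy() == 1.0)

    def test_counting_identity(self, small_sweep):
        sweep, *_ = small_sweep
        freq = selection_frequency(sweep, "hist_gb", 5)
        assert freq.sum() == pytest.approx(5.0)

    def test_injected_informative_feature_selected(self):
        """A planted strong feature is in the top-5 in >=90% of cells."""
        rng = np.random.default_rng(4)
        n = 200
        y = pd.Series(rng.integers(0, 2, n),
                      index=[f"s{i:03d}" for i in range(n)])
        X = pd.DataFrame(rng.normal(size=(n, 40)),
                         index=y.index, columns=[f"f{i:02d}" for i in range(40)])
        X["f13"] = y * 1.5 + rng.normal(0, 0.5, n)
        sweep = run_topk_sweep(X, y, [5], CVPlan(n_folds=5, n_repetitions=4, base_seed=2),
                               models=("enet_lr",))
        freq = selection_frequency(sweep, "enet_lr", 5)
        assert freq.get("f13", 0.0) >= 0.9


class TestFeatureDistributions:
    def test_label_equal_feature_flagged_infinite(self):
        idx = [f"s{i}" for i in range(10)]
        y = pd.Series([0, 1] * 5, index=idx)
        X = pd.DataFrame({"leak": y.astype(float), "noise": np.arange(10.0)}, index=idx)
        out = feature_distributions(X, y, ["leak", "noise"]).set_index("feature")
        assert np.isinf(out.loc["leak", "smd"])
        assert np.isfinite(out.loc["noise", "smd"])

    def test_permutation_invariance(self, small_table):
        table, _ = small_table
        X, _ = split_feature_table(table)
        y = outcome_labels(table, "sex")
        names = list(X.columns[:5])
        a = feature_distributions(X, y, names)
        perm = X.sample(frac=1.0, random_state=3)
        b = feature_distributions(perm, y.loc[perm.index], names)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_feature_rejected(self, small_table):
        table, _ = small_table
        X, _ = split_feature_table(table)
        y = outcome_labels(table, "sex")
        with pytest.raises(Exception):
            feature_distributions(X, y, ["no_such_feature"])
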