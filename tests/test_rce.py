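import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from cpgc import (
    FeatureTable,
    RCEConfig,
    RCESVC,
    cluster_features,
    eliminate_clusters,
    initial_cluster_count,
    run_rce_svm,
    score_clusters,
    split_cohort,
)


def gaussian_table(rng, n0=30, n1=26, f=20, shift=0.0, n_shifted=0):
    values = rng.normal(size=(n0 + n1, f))
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    if n_shifted:
        values[labels == 1, :n_shifted] += shift
    return FeatureTable(values=values, labels=labels, feature_names=[f"f{i}" for i in range(f)])


class TestSplitCohort:
    def test_thirty_twentysix_splits_fifteen_thirteen(self, rng):
        table = gaussian_table(rng)
        train, test = split_cohort(table, seed=0)
        for part in (train, test):
            assert np.sum(part.labels == 0) == 15
            assert np.sum(part.labels == 1) == 13

    def test_partition_is_disjoint_and_complete(self, rng):
        table = gaussian_table(rng)
        train, test = split_cohort(table, seed=1)
        assert set(train.subject_ids).isdisjoint(test.subject_ids)
        assert set(train.subject_ids) | set(test.subject_ids) == set(table.subject_ids)

    def test_deterministic_under_seed(self, rng):
        table = gaussian_table(rng)
        a = split_cohort(table, seed=7)[0].subject_ids
        b = split_cohort(table, seed=7)[0].subject_ids
        assert a == b

    def test_tiny_class_rejected(self, rng):
        table = FeatureTable(
            values=rng.normal(size=(3, 2)), labels=[0, 1, 1], feature_names=["a", "b"]
        )
        with pytest.raises(ValueError, match="class 0"):
            split_cohort(table, seed=0)


class TestClustering:
    def test_initial_count_all_distinct_profiles(self, rng):
        table = gaussian_table(rng, f=10)
        train, _ = split_cohort(table, seed=0)
        assert initial_cluster_count(train, seed=0) == 10

    def test_initial_count_with_duplicate_profiles(self, rng):
        table = gaussian_table(rng, f=10)
        table.values[:, 5] = table.values[:, 2]  # exact duplicate feature
        train, _ = split_cohort(table, seed=0)
        assert initial_cluster_count(train, seed=0) <= 9

    def test_single_feature_returns_one(self, rng):
        table = gaussian_table(rng, f=1)
        assert initial_cluster_count(table, seed=0) == 1

    def test_two_identical_profile_groups_recovered(self, rng):
        base = rng.normal(size=(20, 2))
        values = np.column_stack([base[:, 0]] * 3 + [base[:, 1]] * 3)
        table = FeatureTable(
            values=values, labels=np.repeat([0, 1], 10), feature_names=list("abcdef")
        )
        labels = cluster_features(table, n=2, seed=0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_n_equal_feature_count_gives_singletons(self, rng):
        table = gaussian_table(rng, f=8)
        labels = cluster_features(table, n=8, seed=0)
        assert len(np.unique(labels)) == 8

    def test_n_above_feature_count_rejected(self, rng):
        table = gaussian_table(rng, f=4)
        with pytest.raises(ValueError, match="must lie"):
            cluster_features(table, n=5, seed=0)

    def test_planted_three_cluster_structure_recovered(self):
        # 15 features in 3 groups; profiles = centroid + small noise
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            centroids = rng.normal(scale=3.0, size=(3, 30))
            truth = np.repeat([0, 1, 2], 5)
            profiles = centroids[truth] + rng.normal(scale=0.1, size=(15, 30))
            table = FeatureTable(
                values=profiles.T,
                labels=np.repeat([0, 1], 15),
                feature_names=[f"f{i}" for i in range(15)],
            )
            got = cluster_features(table, n=3, seed=seed)
            if adjusted_rand_score(truth, got) >= 0.9:
                hits += 1
        assert hits >= 18


class TestScoreClusters:
    def test_pure_noise_scores_at_chance(self, null_table):
        assignment = np.zeros(null_table.n_features, dtype=int)
        cfg = RCEConfig(n_folds=5, n_reps=50, seed=0)
        scores, rep_scores = score_clusters(null_table, assignment, cfg)
        assert scores.shape == (1,)
        assert abs(scores[0] - 0.5) < 0.1
        assert rep_scores.shape == (50, 1)

    def test_separating_feature_scores_high(self, rng):
        table = gaussian_table(rng, f=4, shift=4.0, n_shifted=1)
        assignment = np.array([0, 1, 1, 1])
        cfg = RCEConfig(n_folds=5, n_reps=20, seed=0)
        scores, _ = score_clusters(table, assignment, cfg)
        assert scores[0] >= 0.95
        assert scores[0] > scores[1]

    def test_scores_bounded_in_unit_interval(self, planted_table):
        assignment = np.arange(planted_table.n_features) % 5
        cfg = RCEConfig(n_folds=5, n_reps=10, seed=1)
        scores, rep_scores = score_clusters(planted_table, assignment, cfg)
        assert np.all(scores >= 0.0) and np.all(scores <= 1.0)
        assert np.all(rep_scores >= 0.0) and np.all(rep_scores <= 1.0)

    def test_infeasible_fold_count_rejected(self, rng):
        table = gaussian_table(rng, n0=4, n1=4, f=3)
        with pytest.raises(ValueError, match="n_folds"):
            score_clusters(table, np.zeros(3, dtype=int), RCEConfig(n_folds=10, n_reps=5, seed=0))


class TestEliminateClusters:
    def test_twenty_clusters_lose_two(self):
        assignment = np.arange(20)
        scores = np.linspace(0.9, 0.1, 20)
        surviving = eliminate_clusters(assignment, scores, 0.10)
        assert surviving.size == 18
        # the two lowest scores sit at the end of the linspace
        assert set(assignment[surviving]) == set(range(18))

    def test_five_clusters_lose_exactly_one(self):
        assignment = np.repeat(np.arange(5), 2)
        scores = np.array([0.5, 0.4, 0.6, 0.3, 0.7])
        surviving = eliminate_clusters(assignment, scores, 0.10)
        assert set(assignment[surviving]) == {0, 1, 2, 4}

    def test_score_ties_drop_smaller_cluster_id(self):
        assignment = np.arange(4)
        scores = np.array([0.5, 0.5, 0.5, 0.5])
        surviving = eliminate_clusters(assignment, scores, 0.10)
        assert set(assignment[surviving]) == {1, 2, 3}

    def test_single_cluster_is_noop(self):
        assignment = np.zeros(6, dtype=int)
        surviving = eliminate_clusters(assignment, np.array([0.5]), 0.10)
        assert surviving.size == 6


class TestRunRCESVM:
    def test_identical_seed_gives_bit_identical_results(self, planted_table):
        cfg = RCEConfig(n_folds=5, n_reps=10, seed=3)
        r1 = run_rce_svm(planted_table, cfg)
        r2 = run_rce_svm(planted_table, cfg)
        assert [it.evolving_test_accuracy for it in r1.iterations] == [
            it.evolving_test_accuracy for it in r2.iterations
        ]
        assert r1.final_ranking == r2.final_ranking
        assert r1.best_iteration == r2.best_iteration

    def test_monotone_shrinkage_and_termination(self, planted_table):
        res = run_rce_svm(planted_table, RCEConfig(n_folds=5, n_reps=5, seed=0))
        n_clusters = [it.n_clusters for it in res.iterations]
        assert all(a > b for a, b in zip(n_clusters, n_clusters[1:]))
        assert n_clusters[-1] == 1
        for a, b in zip(res.iterations, res.iterations[1:]):
            assert set(b.surviving_feature_names) <= set(a.surviving_feature_names)

    def test_planted_features_selected_and_accurate(self, planted_table):
        res = run_rce_svm(planted_table, RCEConfig(n_folds=5, n_reps=20, seed=1))
        best = res.iterations[res.best_iteration]
        assert res.best_accuracy >= 0.8
        assert {"f0", "f1", "f2"} <= set(best.surviving_feature_names)
        assert res.best_accuracy >= res.baseline_accuracy

    def test_best_iteration_maximizes_accuracy_with_fewest_features(self, planted_table):
        res = run_rce_svm(planted_table, RCEConfig(n_folds=5, n_reps=5, seed=2))
        accs = np.array([it.evolving_test_accuracy for it in res.iterations])
        nfeat = np.array([len(it.surviving_feature_names) for it in res.iterations])
        best = res.best_iteration
        assert accs[best] == accs.max()
        assert nfeat[best] == nfeat[accs == accs.max()].min()

    def test_test_half_never_shapes_selection(self, planted_table):
        """Leakage guard: arbitrarily corrupting the held-out half must not
        change cluster scores or surviving feature sets."""
        cfg = RCEConfig(n_folds=5, n_reps=10, seed=4)
        res_clean = run_rce_svm(planted_table, cfg)
        corrupted = FeatureTable(
            values=planted_table.values.copy(),
            labels=planted_table.labels,
            feature_names=planted_table.feature_names,
            subject_ids=planted_table.subject_ids,
        )
        _, test = split_cohort(planted_table, seed=cfg.seed)
        test_rows = [planted_table.subject_ids.index(s) for s in test.subject_ids]
        corrupted.values[test_rows] = 1e6 * np.sign(corrupted.values[test_rows]) + 13.0
        res_dirty = run_rce_svm(corrupted, cfg)
        assert len(res_clean.iterations) == len(res_dirty.iterations)
        for a, b in zip(res_clean.iterations, res_dirty.iterations):
            assert np.array_equal(a.cluster_scores, b.cluster_scores)
            assert a.surviving_feature_names == b.surviving_feature_names

    def test_chance_behavior_under_label_permutation(self):
        # mean evolving accuracy over null replicates stays at chance
        means = []
        for rep in range(12):
            rng = np.random.default_rng(1000 + rep)
            table = gaussian_table(rng, n0=14, n1=14, f=12)
            res = run_rce_svm(table, RCEConfig(n_folds=5, n_reps=20, seed=rep))
            means.append(np.mean([it.evolving_test_accuracy for it in res.iterations]))
        assert 0.45 <= np.mean(means) <= 0.55

    def test_recluster_each_rep_variant_runs_and_is_deterministic(self, rng):
        table = gaussian_table(rng, n0=12, n1=12, f=8, shift=2.0, n_shifted=2)
        cfg = RCEConfig(n_folds=4, n_reps=5, seed=0, recluster_each_rep=True)
        r1 = run_rce_svm(table, cfg)
        r2 = run_rce_svm(table, cfg)
        assert r1.final_ranking == r2.final_ranking
        assert r1.best_accuracy == r2.best_accuracy


class TestRCESVCEstimator:
    def test_sklearn_api_round_trip(self, planted_table):
        clf = RCESVC(n_folds=5, n_reps=5, random_state=0)
        params = clf.get_params()
        assert params["n_reps"] == 5
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_fit_predict_with_string_labels(self, rng):
        values = rng.normal(size=(24, 6))
        y = np.array(["ctrl"] * 12 + ["case"] * 12)
        values[12:, 0] += 3.0
        clf = RCESVC(n_folds=4, n_reps=5, random_state=1).fit(values, y)
        pred = clf.predict(values)
        assert set(pred) <= {"ctrl", "case"}
        assert clf.score(values, y) > 0.8
        assert hasattr(clf, "result_")
        assert clf.best_features_

    def test_accuracy_curve_and_ranking_tables(self, planted_table):
        clf = RCESVC(n_folds=5, n_reps=5, random_state=0).fit(planted_table)
        curve = clf.result_.accuracy_curve()
        assert list(curve.columns) == ["iteration", "n_clusters", "n_features", "test_accuracy"]
        ranking = clf.result_.ranking_table()
        assert ranking["rank"].tolist() == list(range(1, len(ranking) + 1))
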