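"""Feature selection, corruption, degradation metrics, baselines."""
import numpy as np
import pytest

from tsnegrad import (
    CorruptionPlan,
    DataMatrix,
    ParameterError,
    corrupt,
    metric_ari_kmeans,
    metric_knn10,
    metric_spearman,
    select_features,
)
from tsnegrad.validation import (
    baseline_scores,
    fisher_score,
    laplacian_score,
    random_feature_plan,
)


class TestSelection:
    def test_local_percentile_hand_example(self):
        plan = select_features(np.array([[0.1, 0.9, 0.5]]), "local", fraction=1 / 3)
        assert plan.selected.tolist() == [[1]]

    def test_fraction_one_selects_everything(self):
        scores = np.random.default_rng(0).normal(size=(4, 5))
        for level, labels in [("local", None), ("global", None), ("class", [0, 0, 1, 1])]:
            plan = select_features(scores, level, 1.0, labels=labels)
            mask = plan.cell_mask(4, 5)
            assert mask.all()

    def test_global_counting_hand_example(self):
        A = np.array([[3.0, 1.0, 0.0], [2.0, 1.0, 0.0], [0.0, 1.0, 4.0]])
        plan = select_features(A, "global", fraction=1 / 3)
        assert plan.selected == [0]  # top-1 for two of three samples

    def test_class_counting_uses_member_samples_only(self):
        A = np.array([[3.0, 1.0, 0.0], [2.0, 1.0, 0.0], [0.0, 1.0, 4.0]])
        plan = select_features(A, "class", fraction=1 / 3, labels=["a", "a", "b"])
        assert plan.selected == {"a": [0], "b": [2]}

    def test_empty_selection_errors(self):
        with pytest.raises(ParameterError):
            select_features(np.ones((2, 30)), "local", fraction=0.01)

    def test_tie_break_by_ascending_index(self):
        plan = select_features(np.array([[1.0, 1.0, 1.0, 1.0]]), "local", 0.5)
        assert plan.selected.tolist() == [[0, 1]]


class TestCorruption:
    def test_mean_on_constant_column_is_identity(self):
        X = DataMatrix.from_values(np.column_stack([np.full(4, 2.5), np.arange(4.0)]))
        plan = CorruptionPlan("global", "mean", 0.5, [0])
        out = corrupt(X, plan)
        assert np.allclose(out.values, X.values)

    def test_mean_replaces_with_arithmetic_mean(self):
        X = DataMatrix.from_values(np.array([[1.0], [2.0], [3.0]]))
        plan = CorruptionPlan("global", "mean", 1.0, [0])
        assert np.allclose(corrupt(X, plan).values[:, 0], 2.0)

    def test_class_mean_uses_class_scope(self):
        X = DataMatrix.from_values(np.array([[1.0], [3.0], [10.0], [20.0]]))
        plan = CorruptionPlan(
            "class", "mean", 1.0, {"a": [0], "b": [0]}, labels=np.array(["a", "a", "b", "b"])
        )
        assert np.allclose(corrupt(X, plan).values[:, 0], [2.0, 2.0, 15.0, 15.0])

    def test_permute_is_seeded_and_preserves_multiset(self, rng):
        X = DataMatrix.from_values(rng.normal(size=(10, 3)))
        plan = CorruptionPlan("global", "permute", 1.0, [0, 2])
        o1 = corrupt(X, plan, seed=5)
        o2 = corrupt(X, plan, seed=5)
        assert np.array_equal(o1.values, o2.values)
        for j in (0, 2):
            assert sorted(o1.values[:, j]) == pytest.approx(sorted(X.values[:, j]))
        assert np.array_equal(o1.values[:, 1], X.values[:, 1])

    def test_remove_drops_columns(self, rng):
        X = DataMatrix.from_values(rng.normal(size=(5, 4)))
        plan = CorruptionPlan("global", "remove", 0.5, [1, 3])
        out = corrupt(X, plan)
        assert out.feature_names == [X.feature_names[0], X.feature_names[2]]
        assert np.allclose(out.values, X.values[:, [0, 2]])

    def test_remove_only_global(self):
        with pytest.raises(ParameterError):
            CorruptionPlan("local", "remove", 0.5, [[0]])

    def test_empty_plan_is_identity(self, rng):
        X = DataMatrix.from_values(rng.normal(size=(6, 3)))
        plan = CorruptionPlan("global", "mean", 0.01, [])
        assert np.allclose(corrupt(X, plan).values, X.values)


class TestMetricSpearman:
    def test_identity_and_similarity_invariance(self, rng):
        Y = rng.normal(size=(15, 2))
        assert metric_spearman(Y, Y) == pytest.approx(1.0)
        R = np.array([[0.0, -1.0], [1.0, 0.0]])  # rotation
        assert metric_spearman(Y, 3.0 * Y @ R.T + 5.0) == pytest.approx(1.0)

    def test_reversed_rank_configuration(self):
        # A: one outlier + tight triangle; B: big triangle with a central
        # point -- pairwise distance ranks exactly reversed -> rho = -1
        A = np.array([[10.6, 0.0], [0.0, 0.0], [0.5, 0.0], [0.3, 0.3]])
        B = np.array([[3.8, 4.2], [0.0, 0.0], [10.0, 0.0], [3.0, 10.0]])
        assert metric_spearman(A, B) == pytest.approx(-1.0)

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            metric_spearman(np.zeros((2, 2)), np.zeros((2, 2)))


class TestMetricKnn:
    def test_identity(self, rng):
        Y = rng.normal(size=(15, 2))
        assert metric_knn10(Y, Y) == 1.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            Y1 = rng.normal(size=(14, 2))
            Y2 = rng.normal(size=(14, 2))
            k = 3
            got = metric_knn10(Y1, Y2, k=k)
            vals = []
            for i in range(14):
                d1 = [(np.linalg.norm(Y1[i] - Y1[j]), j) for j in range(14) if j != i]
                d2 = [(np.linalg.norm(Y2[i] - Y2[j]), j) for j in range(14) if j != i]
                s1 = {j for _, j in sorted(d1)[:k]}
                s2 = {j for _, j in sorted(d2)[:k]}
                vals.append(len(s1 & s2) / k)
            assert got == pytest.approx(np.mean(vals))

    def test_tie_break_deterministic(self):
        # three equidistant neighbors, k = 2: lowest indices win, every run
        Y1 = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1], [5, 5], [6, 6], [7, 7],
                       [8, 8], [9, 9], [10, 10], [11, 11]])
        r1 = metric_knn10(Y1, Y1, k=2)
        r2 = metric_knn10(Y1.copy(), Y1.copy(), k=2)
        assert r1 == r2 == 1.0

    def test_n_too_small(self):
        with pytest.raises(ParameterError):
            metric_knn10(np.zeros((5, 2)), np.zeros((5, 2)), k=10)


def _ari_contingency(a, b):
    """Closed-form adjusted Rand index from the contingency table."""
    from math import comb

    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    sum_ij = sum(
        comb(int(np.sum((a == x) & (b == y))), 2)
        for x in np.unique(a)
        for y in np.unique(b)
    )
    sum_a = sum(comb(int(np.sum(a == x)), 2) for x in np.unique(a))
    sum_b = sum(comb(int(np.sum(b == y)), 2) for y in np.unique(b))
    exp = sum_a * sum_b / comb(n, 2)
    mx = (sum_a + sum_b) / 2
    return (sum_ij - exp) / (mx - exp)


class TestMetricAri:
    def test_identity(self, rng):
        Y = rng.normal(size=(30, 2))
        assert metric_ari_kmeans(Y, Y, K=3, seed=0) == 1.0

    def test_hand_contingency_values(self):
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0
        assert adjusted_rand_score([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)
        assert _ari_contingency([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_sklearn_matches_contingency_oracle(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for _ in range(10):
            a = rng.integers(0, 4, size=18)
            b = rng.integers(0, 3, size=18)
            assert adjusted_rand_score(a, b) == pytest.approx(_ari_contingency(a, b))

    def test_n_smaller_than_k(self):
        with pytest.raises(ParameterError):
            metric_ari_kmeans(np.zeros((5, 2)), np.zeros((5, 2)), K=10)


class TestBaselines:
    def test_laplacian_constant_feature_least_informative(self, rng):
        X = np.column_stack([np.full(10, 3.0), rng.normal(size=10)])
        S = np.abs(rng.normal(size=(10, 10)))
        S = (S + S.T) / 2
        scores = laplacian_score(X, S)
        assert scores[0] == np.inf  # zero variation -> ranked last

    def test_fisher_separating_feature_wins(self, rng):
        labels = np.array([0] * 20 + [1] * 20)
        f1 = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
        f2 = rng.normal(0, 1, 40)
        scores = fisher_score(np.column_stack([f1, f2]), labels)
        assert scores[0] > scores[1]

    def test_random_plans_reproducible(self):
        p1 = random_feature_plan(20, "global", 0.2, "mean", seed=7)
        p2 = random_feature_plan(20, "global", 0.2, "mean", seed=7)
        assert p1.selected == p2.selected
        assert len(p1.selected) == 4

    def test_random_local_plans_differ_per_sample(self):
        plan = random_feature_plan(30, "local", 0.2, "mean", seed=1, n_samples=8)
        assert plan.selected.shape == (8, 6)
        assert len({tuple(r) for r in plan.selected}) > 1

    def test_pca_variance_prefers_high_variance_feature(self, rng):
        X = np.column_stack([rng.normal(0, 5, 50), rng.normal(0, 1, 50), rng.normal(0, 0.2, 50)])
        s = baseline_scores(X, "pca_variance")
        assert s[0] > s[1] > s[2]

    def test_fisher_requires_labels(self, rng):
        with pytest.raises(ParameterError):
            baseline_scores(rng.normal(size=(10, 2)), "fisher")

    def test_abs_feature_levels(self, rng):
        X = rng.normal(size=(6, 3))
        assert baseline_scores(X, "abs_feature", level="local").shape == (6, 3)
        assert baseline_scores(X, "abs_feature", level="global").shape == (3,)


class TestClassLevel:
    def test_class_laplacian_recomputed_per_class(self, rng):
        from tsnegrad.validation import class_laplacian_scores

        X = np.vstack([rng.normal(size=(15, 4)), rng.normal(size=(15, 4)) + 3])
        labels = np.array([0] * 15 + [1] * 15)
        scores = class_laplacian_scores(X, labels, matrix="P", perplexity=5)
        assert set(scores) == {0, 1}
        assert all(v.shape == (4,) for v in scores.values())
        # importance orientation: higher = more important (negated score)
        assert np.all(np.isfinite(np.concatenate(list(scores.values()))))

    def test_class_level_experiment_runs(self, rng):
        from tsnegrad import OptimizerConfig
        from tsnegrad.synthetic import SyntheticSpec, generate
        from tsnegrad.validation import run_experiment

        data = generate(SyntheticSpec(n_per_cluster=20, n_clusters=3, d=10,
                                      features_per_cluster=2, shift=4.0, seed=0))
        cfg = OptimizerConfig(n_iter=80, exaggeration_iters=30, exaggeration_factor=4.0,
                              learning_rate=5.0)
        rep = run_experiment(
            data.X, labels=data.labels, selectors=("abs_feature", "random"),
            levels=("class",), methods=("mean", "permute"), fractions=(0.2,),
            n_tsne_seeds=1, perplexity=15, tsne_config=cfg, seed=0,
            n_random_subsets=2,
        )
        assert len(rep.cells) == 6  # (1 + 2 subsets) x 2 methods
        assert rep.cells["spearman"].notna().all()


class TestMetricPermutationInvariance:
    def test_metrics_invariant_to_joint_row_permutation(self, rng):
        Y1 = rng.normal(size=(20, 2))
        Y2 = rng.normal(size=(20, 2))
        perm = rng.permutation(20)
        assert metric_spearman(Y1, Y2) == pytest.approx(metric_spearman(Y1[perm], Y2[perm]))
        assert metric_knn10(Y1, Y2, k=4) == pytest.approx(metric_knn10(Y1[perm], Y2[perm], k=4))
        assert metric_ari_kmeans(Y1, Y2, K=3, seed=0) == pytest.approx(
            metric_ari_kmeans(Y1[perm], Y2[perm], K=3, seed=0)
        )


class TestExperimentSmoke:
    def test_identity_corruption_gives_perfect_metrics(self, rng):
        from tsnegrad import OptimizerConfig, fit
        from tsnegrad.validation import _run_cell

        from tsnegrad.synthetic import SyntheticSpec, generate

        data = generate(SyntheticSpec(n_per_cluster=20, n_clusters=3, d=10,
                                      features_per_cluster=2, shift=4.0, seed=0))
        cfg = OptimizerConfig(n_iter=120, exaggeration_iters=40, exaggeration_factor=4.0,
                              learning_rate=5.0)
        ref = fit(data.X, cfg, perplexity=15, seed=1)
        plan = CorruptionPlan("global", "mean", 0.1, [])
        rec = _run_cell(data.X, plan, cfg, 15, 1, ref.Y, 3)
        assert rec["spearman"] == pytest.approx(1.0)
        assert rec["ari"] == pytest.approx(1.0)
        assert rec["knn10"] == pytest.approx(1.0)

    def test_report_structure(self, rng):
        from tsnegrad import OptimizerConfig
        from tsnegrad.validation import run_experiment
        from tsnegrad.synthetic import SyntheticSpec, generate

        data = generate(SyntheticSpec(n_per_cluster=20, n_clusters=3, d=10,
                                      features_per_cluster=2, shift=4.0, seed=0))
        cfg = OptimizerConfig(n_iter=100, exaggeration_iters=30, exaggeration_factor=4.0,
                              learning_rate=5.0)
        rep = run_experiment(
            data.X, selectors=("abs_feature", "random"), levels=("global",),
            methods=("mean",), fractions=(0.2,), n_tsne_seeds=1, perplexity=15,
            tsne_config=cfg, seed=0, n_random_subsets=2,
        )
        assert len(rep.cells) == 3  # 1 abs_feature + 2 random subsets
        for metric in ("spearman", "ari", "knn10"):
            assert rep.cells[metric].between(-1, 1).all()
        summ = rep.summary(n_boot=100)
        assert {"selector", "fraction", "spearman_lo"} <= set(summ.columns)
        d = rep.to_json_dict()
        assert "metadata" in d and "cells" in d
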