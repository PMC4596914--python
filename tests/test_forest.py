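"""Tree growth, bagging, OOB machinery, and permutation importance."""

import numpy as np
import pytest

from kirimp.forest import (
    Forest,
    ForestParams,
    default_m_try,
    fit_forest,
    grow_tree,
    sqrt_m_try,
)


def brute_force_best_gain(X, y):
    """Exhaustive Gini gain over all SNPs; independent of the tree code."""
    X = np.asarray(X)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)

    def gini_count(labels):
        if len(labels) == 0:
            return 0.0
        _, c = np.unique(labels, return_counts=True)
        return len(labels) * (1.0 - np.sum((c / len(labels)) ** 2))

    parent = gini_count(y)
    gains = {}
    for j in range(X.shape[1]):
        left, right = y[X[:, j] == 0], y[X[:, j] == 1]
        if len(left) == 0 or len(right) == 0:
            continue
        gains[j] = parent - gini_count(left) - gini_count(right)
    return gains


class TestParams:
    def test_subspace_defaults(self):
        assert sqrt_m_try(300) == 17
        assert default_m_try(300) == 100
        assert default_m_try(12) == 10
        assert default_m_try(5) == 5

    def test_m_try_validation(self):
        with pytest.raises(ValueError):
            ForestParams(n_trees=0)
        with pytest.raises(ValueError):
            ForestParams(m_try=0)
        with pytest.raises(ValueError):
            ForestParams(m_try=50).resolve_m_try(10)


class TestGrowTree:
    def test_perfect_tag_gives_depth_one_tree(self, rng):
        X = np.array([[0], [0], [1], [1]], dtype=np.int8)
        y = np.array(["a", "a", "b", "b"])
        tree, classes = grow_tree(X, y, ForestParams(n_trees=1, m_try=1, seed=0), rng)
        assert tree.n_nodes == 3
        assert np.array_equal(classes[tree.predict_codes(X)], y)

    def test_constant_target_single_leaf(self, rng):
        X = np.array([[0, 1], [1, 0]], dtype=np.int8)
        y = np.array([2, 2])
        tree, classes = grow_tree(X, y, ForestParams(n_trees=1, m_try=2, seed=0), rng)
        assert tree.n_nodes == 1
        assert classes[tree.leaf_class[0]] == 2

    def test_root_split_matches_exhaustive_gini(self):
        """Random small instances: the chosen root split attains the brute-force
        optimal Gini gain whenever a positive-gain split exists."""
        rnd = np.random.default_rng(42)
        for _ in range(300):
            n = int(rnd.integers(2, 11))
            p = int(rnd.integers(1, 5))
            X = rnd.integers(0, 2, size=(n, p)).astype(np.int8)
            y = rnd.integers(0, int(rnd.integers(2, 4)), size=n)
            tree, _ = grow_tree(
                X, y, ForestParams(n_trees=1, m_try=p, seed=0),
                np.random.default_rng(int(rnd.integers(1 << 30))),
            )
            gains = brute_force_best_gain(X, y)
            best = max(gains.values()) if gains else 0.0
            if len(np.unique(y)) == 1 or best <= 1e-12:
                assert tree.feature[0] == -1  # leaf: nothing to split on
            else:
                assert tree.feature[0] in gains
                assert gains[tree.feature[0]] == pytest.approx(best)

    def test_each_path_queries_a_snp_at_most_once(self, rng):
        rnd = np.random.default_rng(5)
        X = rnd.integers(0, 2, size=(40, 6)).astype(np.int8)
        y = rnd.integers(0, 3, size=40)
        tree, _ = grow_tree(X, y, ForestParams(n_trees=1, m_try=6, seed=0), rng)

        def walk(node, seen):
            if tree.feature[node] < 0:
                return
            assert tree.feature[node] not in seen
            for child in tree.children[node]:
                walk(child, seen | {tree.feature[node]})

        walk(0, set())

    def test_max_nodes_limits_tree(self, rng):
        rnd = np.random.default_rng(6)
        X = rnd.integers(0, 2, size=(60, 8)).astype(np.int8)
        y = rnd.integers(0, 4, size=60)
        tree, _ = grow_tree(X, y, ForestParams(n_trees=1, m_try=8, max_nodes=5, seed=0), rng)
        assert tree.n_nodes <= 5


class TestFitForest:
    def test_tree_count_and_determinism(self):
        rnd = np.random.default_rng(8)
        X = rnd.integers(0, 2, size=(50, 12)).astype(np.int8)
        y = rnd.integers(0, 2, size=50)
        params = ForestParams(n_trees=25, seed=3)
        f1 = fit_forest(X, y, params)
        f2 = fit_forest(X, y, params)
        assert len(f1.trees) == 25
        Xnew = rnd.integers(0, 2, size=(20, 12)).astype(np.int8)
        assert np.array_equal(f1.predict_proba(Xnew), f2.predict_proba(Xnew))

    def test_missing_values_rejected(self):
        X = np.array([[0, -1], [1, 0]])
        with pytest.raises(ValueError, match="missing"):
            fit_forest(X, [0, 1], ForestParams(n_trees=1, m_try=1, seed=0))

    def test_single_class_warns_and_predicts_it(self):
        X = np.array([[0, 1], [1, 0], [0, 0]], dtype=np.int8)
        with pytest.warns(UserWarning, match="single class"):
            f = fit_forest(X, [5, 5, 5], ForestParams(n_trees=10, seed=0))
        proba = f.predict_proba(X)
        assert np.all(proba == 1.0)
        assert np.all(f.predict(X) == 5)


class TestPredictProba:
    def test_rows_are_vote_fractions(self, noisy_panel):
        panel, truth, _ = noisy_panel
        X = panel.haplotypes.alleles
        y = truth.labels("AvsB").to_numpy().astype(str)
        f = fit_forest(X, y, ForestParams(n_trees=40, seed=1))
        proba = f.predict_proba(X[:30])
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (proba >= 0).all() and (proba <= 1).all()
        # independent per-tree tally
        votes = np.zeros_like(proba)
        for tree in f.trees:
            codes = tree.predict_codes(X[:30])
            for i, c in enumerate(codes):
                votes[i, c] += 1
        assert np.array_equal(proba, votes / 40)

    def test_snp_set_mismatch_reports_missing(self):
        X = np.array([[0, 1], [1, 0]], dtype=np.int8)
        f = fit_forest(X, [0, 1], ForestParams(n_trees=2, m_try=1, seed=0),
                       snp_ids=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            f.predict_proba(X[:, :1], snp_ids=["a"])

    def test_perfect_tag_map_is_tag_class(self):
        X = np.repeat(np.array([[0], [1]], dtype=np.int8), 25, axis=0)
        y = np.repeat([1, 2], 25)
        f = fit_forest(X, y, ForestParams(n_trees=30, m_try=1, seed=0))
        assert np.all(f.predict(np.array([[0]], dtype=np.int8)) == 1)
        assert np.all(f.predict(np.array([[1]], dtype=np.int8)) == 2)


class TestOob:
    def test_single_tree_coverage_near_bootstrap_expectation(self):
        """With one tree, OOB coverage matches (1-1/N)^N ~ e^-1."""
        n = 500
        rnd = np.random.default_rng(10)
        X = rnd.integers(0, 2, size=(n, 5)).astype(np.int8)
        y = rnd.integers(0, 2, size=n)
        fractions = []
        for seed in range(30):
            f = fit_forest(X, y, ForestParams(n_trees=1, m_try=2, seed=seed))
            _, covered, _ = f.oob_predict(X, y)
            fractions.append(covered.mean())
        expected = (1 - 1 / n) ** n
        assert np.mean(fractions) == pytest.approx(expected, abs=0.02)

    def test_perfect_tag_oob_accuracy_high(self, perfect_panel):
        panel, truth, _ = perfect_panel
        X = panel.haplotypes.alleles
        y = truth.labels("KIR2DS2").to_numpy().astype(int)
        f = fit_forest(X, y, ForestParams(n_trees=60, seed=2))
        _, covered, acc = f.oob_predict(X, y)
        assert covered.all()
        assert acc >= 0.99

    def test_oob_close_to_cv_accuracy(self, noisy_panel, small_params):
        """OOB accuracy is an adequate proxy for k-fold cross-validation."""
        from kirimp.evaluation import cross_validate
        from kirimp.panel_io import ReferencePanel

        panel, truth, _ = noisy_panel
        X = panel.haplotypes.alleles
        y = truth.labels("AvsB").to_numpy().astype(str)
        f = fit_forest(X, y, ForestParams(n_trees=150, seed=4))
        _, _, oob_acc = f.oob_predict(X, y)
        reports, _ = cross_validate(panel, params=ForestParams(n_trees=150, seed=4),
                                    loci=["AvsB"], k=5, seed=4)
        assert abs(oob_acc - reports["AvsB"].accuracy) < 0.05


class TestPermutationImportance:
    def _fixture(self):
        rnd = np.random.default_rng(12)
        n = 150
        tag = rnd.integers(0, 2, size=n).astype(np.int8)
        noise = rnd.integers(0, 2, size=(n, 4)).astype(np.int8)
        X = np.column_stack([noise[:, :2], tag, noise[:, 2:]])
        y = tag.copy()
        return X, y

    def test_tag_snp_scores_highest(self):
        X, y = self._fixture()
        f = fit_forest(X, y, ForestParams(n_trees=50, m_try=2, seed=1))
        imp = f.permutation_importance(X, y, np.random.default_rng(1))
        assert np.argmax(imp.score) == 2
        assert imp.score[2] > 2 * np.max(np.abs(np.delete(imp.score, 2)))

    def test_null_snps_score_near_zero(self):
        X, y = self._fixture()
        f = fit_forest(X, y, ForestParams(n_trees=50, m_try=2, seed=1))
        scores = [
            f.permutation_importance(X, y, np.random.default_rng(s)).score
            for s in range(3)
        ]
        null = np.mean([np.delete(s, 2) for s in scores], axis=0)
        assert np.all(np.abs(null) < 1.0)  # well below the tag's normalized score

    def test_unused_snps_score_exactly_zero(self):
        X = np.repeat(np.array([[0, 0], [1, 0]], dtype=np.int8), 20, axis=0)
        y = np.repeat([0, 1], 20)
        f = fit_forest(X, y, ForestParams(n_trees=20, m_try=1, seed=0))
        imp = f.permutation_importance(X, y, np.random.default_rng(0))
        used = set()
        for t in f.trees:
            used |= set(t.used_features().tolist())
        for j in range(2):
            if j not in used:
                assert imp.score[j] == 0.0
        assert np.isfinite(imp.score).all()


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        rnd = np.random.default_rng(14)
        X = rnd.integers(0, 2, size=(40, 6)).astype(np.int8)
        y = rnd.integers(0, 3, size=40)
        f = fit_forest(X, y, ForestParams(n_trees=15, seed=9), snp_ids=[f"s{i}" for i in range(6)])
        back = Forest.from_dict(f.to_dict())
        assert np.array_equal(back.predict_proba(X), f.predict_proba(X))
        assert back.snp_ids == f.snp_ids


class TestAgainstSklearn:
    def test_accuracy_comparable_to_reference_forest(self, noisy_panel):
        """Independent cross-check: a standard RF implementation reaches
        similar OOB accuracy on the same task."""
        sklearn = pytest.importorskip("sklearn.ensemble")
        panel, truth, _ = noisy_panel
        X = panel.haplotypes.alleles
        y = truth.labels("KIRhaplotype").to_numpy().astype(str)
        f = fit_forest(X, y, ForestParams(n_trees=200, seed=6))
        _, _, ours = f.oob_predict(X, y)
        ref = sklearn.RandomForestClassifier(
            n_estimators=200, max_features=f.params.resolve_m_try(X.shape[1]),
            oob_score=True, random_state=6,
        ).fit(X, y)
        assert abs(ours - ref.oob_score_) < 0.05
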