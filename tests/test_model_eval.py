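import json

import numpy as np
import pandas as pd
import pytest

from pepqsar.descriptors import DescriptorMatrix, featurize_dataset, remove_zero_features
from pepqsar.io import ANTI, NON_ANTI
from pepqsar.model_eval import (
    FAMILIES,
    LearnerSpec,
    NestedCVConfig,
    _build_estimator,
    _fit,
    aggregate,
    compute_accuracy,
    compute_auc,
    make_default_learners,
    make_fast_learners,
    performance_blocks,
    run_nested_cv,
)

from conftest import make_dataset


def auc_pair_counting(scores, y):
    """Brute-force Mann-Whitney: count positive-over-negative pairs."""
    pos = [s for s, yy in zip(scores, y) if yy == 1]
    neg = [s for s, yy in zip(scores, y) if yy == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestDefaultGrids:
    def test_rf_mtry_upper_limit(self):
        (rf,) = make_default_learners(3058, families=("RF",))
        assert rf.grid["mtry"] == list(range(1, 56))  # floor(sqrt(3058)) = 55
        assert rf.grid["nodesize"] == [1, 2, 3]
        assert rf.fixed["ntree"] == 1000

    def test_svm_grid_625_points(self):
        (svm,) = make_default_learners(100, families=("SVM_RBF",))
        assert len(list(svm.grid_points())) == 625
        assert min(svm.grid["C"]) == 2**-12 and max(svm.grid["sigma"]) == 2**12

    def test_glmnet_grid_45_points(self):
        (gl,) = make_default_learners(100, families=("GLMNET",))
        assert len(list(gl.grid_points())) == 45
        assert gl.grid["alpha"] == [0.0001, 0.001, 0.01, 0.1, 1]
        assert gl.grid["lambda"] == [0, 0.15, 0.25, 0.35, 0.5, 0.65, 0.75, 0.85, 1]

    def test_knn_grid(self):
        (knn,) = make_default_learners(100, families=("KNN_WEIGHTED",))
        assert knn.grid["k"] == [1, 2, 3, 4, 5]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown learner family"):
            LearnerSpec("GBM", grid={})


class TestAUC:
    def test_perfect_ranking(self):
        assert compute_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties_half(self):
        assert compute_auc(np.zeros(6), np.array([1, 1, 1, 0, 0, 0])) == 0.5

    def test_fixed_examples(self):
        y = np.array([1, 0, 1, 0])
        assert compute_auc(np.array([3, 1, 2, 0]), y) == 1.0
        # positives score {3, 1}, negatives {2, 0}: 3 of 4 pairs correct
        assert compute_auc(np.array([3, 2, 1, 0]), y) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_string_labels_anti_positive(self):
        scores = np.array([0.9, 0.1])
        assert compute_auc(scores, np.array([ANTI, NON_ANTI])) == 1.0

    def test_oracle_equivalence_random(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = np.zeros(n, dtype=int)
            y[: max(1, n // 3)] = 1
            rng.shuffle(y)
            scores = rng.choice(np.arange(6), size=n).astype(float)  # ties likely
            if y.sum() in (0, n):
                continue
            assert compute_auc(scores, y) == pytest.approx(auc_pair_counting(scores, y))


class TestAccuracy:
    def test_basic(self):
        assert compute_accuracy(np.array([1, 0, 1]), np.array([1, 0, 1])) == 1.0
        assert compute_accuracy(np.array([1, 0]), np.array([0, 1])) == 0.0
        assert compute_accuracy(np.array([1, 0, 1, 1]), np.array([1, 0, 1, 0])) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_accuracy(np.array([1]), np.array([1, 0]))


class TestGlmnetMapping:
    def test_lambda_zero_matches_unpenalized(self, rng):
        """With lambda=0 the elastic-net learner reduces to plain logistic
        regression on a small well-conditioned problem."""
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
        est = _build_estimator("GLMNET", {"alpha": 1, "lambda": 0}, {}, 0, len(y))
        _fit(est, X, y)
        ref = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000).fit(X, y)
        # saga vs lbfgs on a near-separable direction: compare with a
        # relative tolerance since the dominant coefficient is large
        assert np.allclose(est.coef_, ref.coef_, rtol=1e-2, atol=1e-2)


def separable_dataset():
    # positives use one residue vocabulary, negatives a disjoint one
    rng = np.random.default_rng(0)
    pos = ["".join(rng.choice(list("ACDEF"), size=12)) for _ in range(30)]
    neg = ["".join(rng.choice(list("GHIKL"), size=12)) for _ in range(30)]
    return make_dataset({ANTI: pos, NON_ANTI: neg})


class TestRunNestedCV:
    @pytest.fixture(scope="class")
    def separable_results(self):
        ds = separable_dataset()
        m = remove_zero_features(featurize_dataset(ds, sets=("aac",)))
        cfg = NestedCVConfig(outer_folds=3, outer_repeats=2, seed=1)
        return run_nested_cv(
            m, ds.label_vector(), make_fast_learners(m.p), cfg, dataset_label="sep"
        )

    def test_separable_all_learners_high_auc(self, separable_results):
        summary = aggregate(separable_results)
        assert (summary["mean_auc"] >= 0.95).all()

    def test_complete_fold_coverage(self, separable_results):
        counts = separable_results.results.groupby(["learner", "repeat"]).size()
        assert (counts == 3).all()
        assert set(separable_results.results["learner"]) == set(FAMILIES)

    def test_glmnet_coefficients_recorded(self, separable_results):
        coefs = separable_results.coefficients
        assert set(coefs["learner"]) == {"GLMNET"}
        assert (
            coefs.groupby(["repeat", "fold"]).size() > 0
        ).all()

    def test_params_recorded_as_json(self, separable_results):
        for s in separable_results.results["params"]:
            assert isinstance(json.loads(s), dict)

    def test_determinism(self):
        ds = separable_dataset()
        m = remove_zero_features(featurize_dataset(ds, sets=("aac",)))
        cfg = NestedCVConfig(outer_folds=3, outer_repeats=1, seed=5)
        learners = make_fast_learners(m.p, families=("GLMNET", "KNN_WEIGHTED"))
        a = run_nested_cv(m, ds.label_vector(), learners, cfg)
        b = run_nested_cv(m, ds.label_vector(), learners, cfg)
        pd.testing.assert_frame_equal(a.results, b.results)
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients)

    def test_stratified_partition_covers_each_record_once(self):
        ds = separable_dataset()
        m = remove_zero_features(featurize_dataset(ds, sets=("aac",)))
        from sklearn.model_selection import StratifiedKFold
        from pepqsar.model_eval import _child_seed

        y = (np.array(ds.label_vector()) == ANTI).astype(int)
        cfg = NestedCVConfig(outer_folds=5, outer_repeats=2, seed=9)
        for repeat in range(cfg.outer_repeats):
            skf = StratifiedKFold(5, shuffle=True, random_state=_child_seed(cfg.seed, repeat))
            seen = np.concatenate([te for _, te in skf.split(np.zeros(len(y)), y)])
            assert sorted(seen) == list(range(len(y)))
            for _, te in skf.split(np.zeros(len(y)), y):
                frac = y[te].mean()
                assert abs(frac - y.mean()) <= 1.0 / len(te)

    def test_single_class_input_rejected(self):
        m = DescriptorMatrix(["a", "b"], ["AAC:A"], np.ones((2, 1)))
        with pytest.raises(ValueError, match=">= 2 rows"):
            run_nested_cv(m, [ANTI, ANTI], make_fast_learners(1), NestedCVConfig(2, 1))

    def test_nonfinite_rejected(self):
        m = DescriptorMatrix(
            ["a", "b", "c", "d"], ["AAC:A"], np.array([[1.0], [np.nan], [0.0], [2.0]])
        )
        with pytest.raises(ValueError, match="non-finite"):
            run_nested_cv(
                m, [ANTI, ANTI, NON_ANTI, NON_ANTI], make_fast_learners(1), NestedCVConfig(2, 1)
            )


class TestAggregate:
    def _table(self, aucs_by_repeat):
        rows = []
        for r, aucs in enumerate(aucs_by_repeat):
            for f, a in enumerate(aucs):
                rows.append(
                    dict(repeat=r, fold=f, learner="RF", dataset="d", auc=a, accuracy=a, params="{}")
                )
        from pepqsar.model_eval import ResultTable

        return ResultTable(
            results=pd.DataFrame(rows),
            coefficients=pd.DataFrame(columns=["repeat", "fold", "learner", "dataset", "feature", "beta"]),
            config=NestedCVConfig(outer_folds=len(aucs_by_repeat[0]), outer_repeats=len(aucs_by_repeat)),
        )

    def test_constant_folds(self):
        t = self._table([[0.8, 0.8], [0.8, 0.8]])
        s = aggregate(t)
        assert s.loc[0, "mean_auc"] == pytest.approx(0.8)
        assert s.loc[0, "sd_auc"] == pytest.approx(0.0)

    def test_mean_of_repeat_means(self):
        t = self._table([[0.7, 0.7], [0.8, 0.8], [0.9, 0.9], [0.8, 0.8], [0.8, 0.8]])
        assert aggregate(t).loc[0, "mean_auc"] == pytest.approx(0.8)

    def test_matches_bruteforce_reduction(self, rng):
        aucs = rng.uniform(0.5, 1.0, size=(4, 6))
        t = self._table(aucs.tolist())
        got = aggregate(t).loc[0, "mean_auc"]
        assert got == pytest.approx(np.mean([np.mean(r) for r in aucs]))

    def test_incomplete_coverage_errors(self):
        t = self._table([[0.8, 0.8], [0.8, 0.8]])
        t.results = t.results.iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            aggregate(t)


def test_performance_blocks_shapes():
    rows = []
    for learner in ("RF", "GLMNET"):
        for r in range(3):
            for f in range(2):
                rows.append(
                    dict(repeat=r, fold=f, learner=learner, dataset="d",
                         auc=0.5 + 0.01 * r, accuracy=0.5, params="{}")
                )
    from pepqsar.model_eval import ResultTable

    t = ResultTable(pd.DataFrame(rows), pd.DataFrame(), NestedCVConfig(2, 3))
    by_repeat = performance_blocks([t], blocks="repeat")
    assert by_repeat.shape == (3, 2)
    by_fold = performance_blocks([t], blocks="fold")
    assert by_fold.shape == (6, 2)
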