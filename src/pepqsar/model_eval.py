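"""Nested-resampling benchmarking of four learner families.

The evaluation protocol wraps hyperparameter tuning inside performance
estimation: an outer stratified 10-fold cross-validation repeated 5 times
estimates generalization, while a single inner stratified 2/3-1/3 holdout
of each outer-training set scores every hyperparameter grid point (by
inner-validation AUC) and picks the configuration refit on the full
outer-training set. Feature selection and standardization can be performed
inside each outer-training fold (leakage-safe default) or once globally
(matching a simpler, study-faithful workflow); both are supported.

Learner families and default tuning grids:

* RF — random forest, 1000 trees; mtry in 1..floor(sqrt(p)), terminal node
  size 1-3.
* KNN_WEIGHTED — distance-weighted k-nearest neighbours, k in 1..5.
* SVM_RBF — RBF-kernel SVM, C and the kernel width parameter on the grid
  2^-12 .. 2^12 (step: powers of two).
* GLMNET — elastic-net-penalized logistic regression, mixing parameter
  alpha in {0.0001, 0.001, 0.01, 0.1, 1} and penalty strength lambda in
  {0, 0.15, 0.25, 0.35, 0.5, 0.65, 0.75, 0.85, 1}; fitted coefficients are
  recorded per fold for downstream importance analysis.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .descriptors import DescriptorMatrix, fit_standardizer
from .feature_selection import rank_features_ttest, select_top_k
from .io import ANTI, NON_ANTI

FAMILIES = ("RF", "KNN_WEIGHTED", "SVM_RBF", "GLMNET")

#: ANTI is the positive class throughout: scores and AUC are oriented so
#: larger means more anti-angiogenic, and GLMNET coefficient signs are
#: reported under this encoding (positive beta -> pushes toward ANTI).
POSITIVE_LABEL = ANTI


@dataclass
class LearnerSpec:
    family: str
    grid: dict[str, list]
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; expected {FAMILIES}")

    def grid_points(self):
        """Fixed iteration order: insertion order of grid keys."""
        keys = list(self.grid)
        for combo in itertools.product(*(self.grid[k] for k in keys)):
            yield dict(zip(keys, combo))


@dataclass
class NestedCVConfig:
    outer_folds: int = 10
    outer_repeats: int = 5
    inner_val_fraction: float = 1.0 / 3.0
    stratified: bool = True
    seed: int = 0


@dataclass
class ResultTable:
    """Per-(repeat, fold, learner, dataset) outcomes of a nested-CV run.

    ``results`` columns: repeat, fold, learner, dataset, auc, accuracy,
    params (JSON string). ``coefficients`` (GLMNET only) columns: repeat,
    fold, learner, dataset, feature, beta.
    """

    results: pd.DataFrame
    coefficients: pd.DataFrame
    config: NestedCVConfig

    def to_csv(self, results_path, coefficients_path=None) -> None:
        self.results.to_csv(results_path, index=False)
        if coefficients_path is not None:
            self.coefficients.to_csv(coefficients_path, index=False)


def make_default_learners(p_max: int, families: tuple[str, ...] = FAMILIES) -> list[LearnerSpec]:
    """The full tuning grids for each requested learner family."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    mtry_max = max(1, int(np.floor(np.sqrt(p_max))))
    pow2 = [2.0**i for i in range(-12, 13)]
    specs = {
        "RF": LearnerSpec(
            "RF",
            grid={"mtry": list(range(1, mtry_max + 1)), "nodesize": [1, 2, 3]},
            fixed={"ntree": 1000},
        ),
        "KNN_WEIGHTED": LearnerSpec("KNN_WEIGHTED", grid={"k": [1, 2, 3, 4, 5]}),
        "SVM_RBF": LearnerSpec("SVM_RBF", grid={"C": pow2, "sigma": pow2}),
        "GLMNET": LearnerSpec(
            "GLMNET",
            grid={
                "alpha": [0.0001, 0.001, 0.01, 0.1, 1],
                "lambda": [0, 0.15, 0.25, 0.35, 0.5, 0.65, 0.75, 0.85, 1],
            },
        ),
    }
    return [specs[f] for f in families]


def make_fast_learners(p_max: int, families: tuple[str, ...] = FAMILIES) -> list[LearnerSpec]:
    """Reduced grids for quick runs: same families, coarse hyperparameters."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    mtry_max = max(1, int(np.floor(np.sqrt(p_max))))
    specs = {
        "RF": LearnerSpec(
            "RF",
            grid={"mtry": sorted({1, mtry_max}), "nodesize": [1]},
            fixed={"ntree": 100},
        ),
        "KNN_WEIGHTED": LearnerSpec("KNN_WEIGHTED", grid={"k": [1, 3, 5]}),
        "SVM_RBF": LearnerSpec(
            "SVM_RBF", grid={"C": [2.0**i for i in (-4, 0, 4)], "sigma": [2.0**i for i in (-8, -4, 0)]}
        ),
        "GLMNET": LearnerSpec(
            "GLMNET", grid={"alpha": [0.01, 0.1, 1], "lambda": [0, 0.15, 0.5]}
        ),
    }
    return [specs[f] for f in families]


def compute_auc(scores: np.ndarray, labels: np.ndarray | list[str]) -> float:
    """AUC = normalized Mann-Whitney U; ties contribute 1/2.

    Labels may be strings (ANTI positive) or binary 0/1.
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        y = (labels == POSITIVE_LABEL).astype(int)
    else:
        y = labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(y, scores))


def compute_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    if predicted.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.mean(predicted == truth))


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _build_estimator(family: str, params: dict, fixed: dict, seed: int, n_samples: int):
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=fixed.get("ntree", 1000),
            max_features=params["mtry"],
            min_samples_leaf=params["nodesize"],
            random_state=seed,
            n_jobs=1,
        )
    if family == "KNN_WEIGHTED":
        return KNeighborsClassifier(
            n_neighbors=params["k"], weights="distance", metric="minkowski"
        )
    if family == "SVM_RBF":
        return SVC(kernel="rbf", C=params["C"], gamma=params["sigma"], random_state=seed)
    if family == "GLMNET":
        lam = params["lambda"]
        # glmnet objective (1/N) sum loss + lambda * P maps to sklearn's
        # sum loss + (1/C) * P via C = 1 / (N * lambda); lambda=0 is
        # approximated by a very large C (effectively unpenalized).
        C = 1.0 / (n_samples * lam) if lam > 0 else 1e10
        return LogisticRegression(
            solver="saga",
            l1_ratio=params["alpha"],
            C=C,
            max_iter=5000,
            random_state=seed,
        )
    raise ValueError(f"unknown family {family!r}")


def _scores(est, family: str, X: np.ndarray) -> np.ndarray:
    if family == "SVM_RBF":
        return est.decision_function(X)
    return est.predict_proba(X)[:, 1]


def _fit(est, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def run_nested_cv(
    matrix: DescriptorMatrix,
    labels: list[str] | np.ndarray,
    learners: list[LearnerSpec],
    config: NestedCVConfig,
    fs_k: int | None = None,
    fs_mode: str = "fold",
    standardize_mode: str = "fold",
    dataset_label: str = "dataset",
) -> ResultTable:
    """Run the nested-resampling benchmark.

    ``fs_k`` requests top-k t-test filter selection; ``fs_mode`` and
    ``standardize_mode`` choose between per-outer-fold (leakage-safe) and
    global (fit once on all rows) artifacts; ``"none"`` disables
    standardization.
    """
    labels = np.asarray(labels)
    y = (labels == POSITIVE_LABEL).astype(int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 rows in each class")
    if not np.isfinite(matrix.values).all():
        raise ValueError("descriptor matrix contains non-finite values")
    if fs_mode not in ("fold", "global") or standardize_mode not in ("fold", "global", "none"):
        raise ValueError(f"unknown mode: fs_mode={fs_mode!r}, standardize_mode={standardize_mode!r}")

    # global (study-faithful) artifacts are fit once on all rows
    work = matrix
    if fs_k is not None and fs_mode == "global":
        ranking = rank_features_ttest(work, labels)
        work = select_top_k(ranking, work, fs_k)
    X_all = work.values
    if standardize_mode == "global":
        std = fit_standardizer(work)
        X_all = std.transform(X_all)

    rows: list[dict] = []
    coef_rows: list[dict] = []
    n = len(y)

    for repeat in range(config.outer_repeats):
        skf = StratifiedKFold(
            n_splits=config.outer_folds,
            shuffle=True,
            random_state=_child_seed(config.seed, repeat),
        )
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError("a class is absent from an outer training fold")
            # per-fold feature selection / standardization on training rows only
            if fs_k is not None and fs_mode == "fold":
                train_mat = DescriptorMatrix(
                    [matrix.peptide_ids[i] for i in train_idx],
                    list(matrix.feature_names),
                    matrix.values[train_idx],
                )
                ranking = rank_features_ttest(train_mat, labels[train_idx])
                selected = ranking.ordered_features[:fs_k]
                col_idx = [matrix.feature_names.index(f) for f in selected]
                X_fold = matrix.values[:, col_idx]
                feat_names = selected
            else:
                X_fold = X_all
                feat_names = list(work.feature_names)

            if standardize_mode == "fold":
                mu = X_fold[train_idx].mean(axis=0)
                sd = X_fold[train_idx].std(axis=0, ddof=1)
                sd_safe = np.where(sd == 0, 1.0, sd)
                X_use = (X_fold - mu) / sd_safe
                X_use[:, sd == 0] = 0.0
            else:
                X_use = X_fold

            X_train, y_train = X_use[train_idx], y[train_idx]
            X_test, y_test = X_use[test_idx], y[test_idx]

            for li, spec in enumerate(learners):
                seed = _child_seed(config.seed, repeat, fold, li)
                tr_in, va_in = train_test_split(
                    np.arange(len(train_idx)),
                    test_size=config.inner_val_fraction,
                    stratify=y_train if config.stratified else None,
                    random_state=seed,
                )
                best_auc, best_params = -np.inf, None
                for params in spec.grid_points():
                    est = _build_estimator(spec.family, params, spec.fixed, seed, len(tr_in))
                    _fit(est, X_train[tr_in], y_train[tr_in])
                    s = _scores(est, spec.family, X_train[va_in])
                    if len(np.unique(y_train[va_in])) < 2:
                        raise ValueError("inner validation split lost a class")
                    auc_in = roc_auc_score(y_train[va_in], s)
                    if auc_in > best_auc:  # first-best wins ties
                        best_auc, best_params = auc_in, params

                est = _build_estimator(
                    spec.family, best_params, spec.fixed, seed, len(train_idx)
                )
                _fit(est, X_train, y_train)
                s_test = _scores(est, spec.family, X_test)
                auc = roc_auc_score(y_test, s_test)
                if spec.family == "SVM_RBF":
                    y_pred = est.predict(X_test)
                else:
                    y_pred = (s_test >= 0.5).astype(int)
                acc = compute_accuracy(y_pred, y_test)
                rows.append(
                    {
                        "repeat": repeat,
                        "fold": fold,
                        "learner": spec.family,
                        "dataset": dataset_label,
                        "auc": auc,
                        "accuracy": acc,
                        "params": json.dumps(best_params, sort_keys=True),
                    }
                )
                if spec.family == "GLMNET":
                    for fname, beta in zip(feat_names, est.coef_.ravel()):
                        coef_rows.append(
                            {
                                "repeat": repeat,
                                "fold": fold,
                                "learner": spec.family,
                                "dataset": dataset_label,
                                "feature": fname,
                                "beta": float(beta),
                            }
                        )

    results = pd.DataFrame(rows)
    coefficients = pd.DataFrame(
        coef_rows, columns=["repeat", "fold", "learner", "dataset", "feature", "beta"]
    )
    return ResultTable(results=results, coefficients=coefficients, config=config)


def aggregate(table: ResultTable) -> pd.DataFrame:
    """Summaries per (learner, dataset): repeat means and the overall mean.

    The reported performance is the mean over the outer folds within each
    repeat, then the mean of those repeat means; dispersion is the standard
    deviation of the repeat means. Raises if any (learner, dataset, repeat)
    group is missing folds.
    """
    df = table.results
    expected = table.config.outer_folds
    counts = df.groupby(["learner", "dataset", "repeat"]).size()
    bad = counts[counts != expected]
    if len(bad):
        raise ValueError(f"incomplete fold coverage: {bad.to_dict()}")
    per_repeat = (
        df.groupby(["learner", "dataset", "repeat"])[["auc", "accuracy"]]
        .mean()
        .reset_index()
    )
    overall = (
        per_repeat.groupby(["learner", "dataset"])
        .agg(
            mean_auc=("auc", "mean"),
            sd_auc=("auc", "std"),
            mean_accuracy=("accuracy", "mean"),
            sd_accuracy=("accuracy", "std"),
            n_repeats=("repeat", "nunique"),
        )
        .reset_index()
    )
    return overall


def performance_blocks(
    tables: list[ResultTable], metric: str = "auc", blocks: str = "repeat"
) -> pd.DataFrame:
    """Pivot fold results into an N-blocks x k-models matrix for comparison.

    Model columns are labeled "<learner>/<dataset>". ``blocks="repeat"``
    uses per-repeat fold means (N = outer repeats); ``blocks="fold"`` uses
    raw per-fold values (N = repeats x folds).
    """
    if blocks not in ("repeat", "fold"):
        raise ValueError("blocks must be 'repeat' or 'fold'")
    df = pd.concat([t.results for t in tables], ignore_index=True)
    df["model"] = df["learner"] + "/" + df["dataset"]
    if blocks == "repeat":
        df = df.groupby(["model", "repeat"])[metric].mean().reset_index()
        wide = df.pivot(index="repeat", columns="model", values=metric)
    else:
        wide = df.pivot_table(index=["repeat", "fold"], columns="model", values=metric)
    if wide.isna().any().any():
        raise ValueError("models do not share a complete block design")
    return wide
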