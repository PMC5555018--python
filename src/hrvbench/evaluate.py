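"""Repeated stratified cross-validated classifier comparison.

Eight classifier families/configurations (nine fitted models) are
compared on every accepted feature combination: linear and quadratic
discriminant analysis, k-nearest neighbors with k = 3, 4, 5, an RBF
support-vector machine (γ = 2, C = 1), decision trees with depth cap 5
and uncapped, and Gaussian naive Bayes. Accuracy is measured by
stratified 5-fold cross-validation repeated with fresh random folds
(default 100 repetitions); each repetition's score is the mean of its
fold accuracies, and the reported value is the mean ± SD over repetition
scores, on the percent scale.

Also provided: ranking of (classifier, combination) results,
feature-occurrence tables over high-scoring combinations, and a PCA
baseline (z-scored features, combinations of the first 10 principal
components evaluated the same way).
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .combsearch import Combination

N_FOLDS = 5
N_REPEATS = 100


@dataclass(frozen=True)
class ClassifierSpec:
    """One named classifier configuration."""

    name: str
    family: str
    params: tuple = ()

    def build(self):
        if self.family == "linear-discriminant":
            return LinearDiscriminantAnalysis()
        if self.family == "quadratic-discriminant":
            # tiny ridge keeps near-singular class covariances invertible
            return QuadraticDiscriminantAnalysis(reg_param=1e-6)
        if self.family == "k-nearest-neighbors":
            return KNeighborsClassifier(n_neighbors=dict(self.params)["k"])
        if self.family == "svm-rbf":
            p = dict(self.params)
            return SVC(gamma=p.get("gamma", 2.0), C=p.get("C", 1.0))
        if self.family == "decision-tree":
            return DecisionTreeClassifier(
                max_depth=dict(self.params).get("max_depth"), random_state=0)
        if self.family == "gaussian-naive-bayes":
            return GaussianNB()
        raise ValueError(f"unknown classifier family {self.family!r}")


def default_classifiers() -> list[ClassifierSpec]:
    """The nine benchmark configurations."""
    return [
        ClassifierSpec("LDA", "linear-discriminant"),
        ClassifierSpec("QDA", "quadratic-discriminant"),
        ClassifierSpec("NN3", "k-nearest-neighbors", (("k", 3),)),
        ClassifierSpec("NN4", "k-nearest-neighbors", (("k", 4),)),
        ClassifierSpec("NN5", "k-nearest-neighbors", (("k", 5),)),
        ClassifierSpec("RBF SVM", "svm-rbf", (("gamma", 2.0), ("C", 1.0))),
        ClassifierSpec("DT depth5", "decision-tree", (("max_depth", 5),)),
        ClassifierSpec("DT", "decision-tree", (("max_depth", None),)),
        ClassifierSpec("NB", "gaussian-naive-bayes"),
    ]


@dataclass
class CVResult:
    classifier: ClassifierSpec
    combination: Combination
    mean_accuracy: float  # percent
    sd_accuracy: float  # percent, over repetitions
    n_repeats: int
    n_folds: int
    seed: int

    def formatted(self) -> str:
        return f"{self.mean_accuracy:.2f} ± {self.sd_accuracy:.2f}"


def make_folds(labels, k: int = N_FOLDS, seed: int = 0) -> np.ndarray:
    """Stratified random partition into k folds; returns fold id per subject.

    Every class is split as evenly as possible across folds (a 30 + 40
    cohort with k = 5 puts exactly 6 + 8 subjects in each fold).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("stratified folds need >= 2 classes")
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} < k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_id = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        fold_id[test_idx] = fold
    return fold_id


class _RegularizedQDA:
    """Class-conditional Gaussian classifier with ridge-stabilized covariance.

    Fallback for quadratic discriminant analysis when a class covariance is
    rank deficient (fewer samples than features in a training fold): each
    class covariance gets a ridge λ·I with λ = 1e-6·trace/d, escalated
    tenfold until the matrix factorizes.
    """

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        d = x.shape[1]
        self._models = []
        for c in self.classes_:
            xc = x[y == c]
            mu = xc.mean(axis=0)
            cov = np.atleast_2d(np.cov(xc.T, ddof=1)) if xc.shape[0] > 1 \
                else np.eye(d)
            lam = max(1e-6 * np.trace(cov) / d, 1e-12)
            while True:
                try:
                    np.linalg.cholesky(cov + lam * np.eye(d))
                    break
                except np.linalg.LinAlgError:
                    lam *= 10.0
            reg = cov + lam * np.eye(d)
            sign, logdet = np.linalg.slogdet(reg)
            self._models.append((mu, np.linalg.inv(reg), logdet,
                                 np.log(xc.shape[0] / x.shape[0])))
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        scores = np.empty((x.shape[0], len(self.classes_)))
        for j, (mu, prec, logdet, logprior) in enumerate(self._models):
            diff = x - mu
            maha = np.einsum("ij,jk,ik->i", diff, prec, diff)
            scores[:, j] = logprior - 0.5 * (maha + logdet)
        return self.classes_[np.argmax(scores, axis=1)]


def fit_predict(spec: ClassifierSpec, x_train, y_train, x_test) -> np.ndarray:
    """Fit one configuration on the training block, predict the test block."""
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.asarray(x_test, dtype=float)
    if np.unique(np.asarray(y_train)).size < 2:
        raise ValueError("training block must contain both classes")
    if not (np.all(np.isfinite(x_train)) and np.all(np.isfinite(x_test))):
        raise ValueError("feature columns must be finite")
    model = spec.build()
    try:
        model.fit(x_train, y_train)
    except np.linalg.LinAlgError:
        # singular class covariance (few samples / collinear features):
        # fall back to a regularized discriminant fit
        if spec.family == "linear-discriminant":
            model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            model.fit(x_train, y_train)
        elif spec.family == "quadratic-discriminant":
            model = _RegularizedQDA().fit(x_train, y_train)
        else:
            raise
    return model.predict(x_test)


def repeated_cv(table: pd.DataFrame, combination: Combination | list[str],
                spec: ClassifierSpec, repeats: int = N_REPEATS,
                k: int = N_FOLDS, seed: int = 0,
                label_col: str = "label", scale: bool = False,
                sd_mode: str = "repetitions") -> CVResult:
    """Repeated stratified k-fold accuracy of one (classifier, combination).

    Per repetition: fresh stratified folds, accuracy per fold, repetition
    score = mean of the k fold accuracies. Reported mean and SD are over
    the ``repeats`` repetition scores (percent); ``sd_mode="folds"``
    spreads over all repeats·k fold scores instead. ``scale`` z-scores
    each training block and applies its statistics to the test block.
    Repetition seeds are derived from the master seed.
    """
    if isinstance(combination, Combination):
        cols = list(combination.feature_names)
    else:
        cols = list(combination)
        combination = Combination(tuple(cols), float("nan"))
    if sd_mode not in ("repetitions", "folds"):
        raise ValueError("sd_mode must be 'repetitions' or 'folds'")
    x = table[cols].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    rng = np.random.default_rng(seed)
    rep_scores = np.empty(repeats)
    all_fold_scores = np.empty((repeats, k))
    for rep in range(repeats):
        rep_seed = int(rng.integers(2 ** 31))
        fold_id = make_folds(y, k=k, seed=rep_seed)
        fold_acc = np.empty(k)
        for fold in range(k):
            test = fold_id == fold
            x_train, x_test = x[~test], x[test]
            if scale:
                mu = x_train.mean(axis=0)
                sigma = x_train.std(axis=0, ddof=1)
                sigma[sigma == 0] = 1.0
                x_train = (x_train - mu) / sigma
                x_test = (x_test - mu) / sigma
            pred = fit_predict(spec, x_train, y[~test], x_test)
            fold_acc[fold] = np.mean(pred == y[test])
        all_fold_scores[rep] = fold_acc
        rep_scores[rep] = fold_acc.mean()
    if sd_mode == "folds" or repeats == 1:
        # spread over individual fold scores
        sd = float(np.std(all_fold_scores.ravel(), ddof=1)) * 100.0
    else:
        sd = float(np.std(rep_scores, ddof=1)) * 100.0
    return CVResult(classifier=spec, combination=combination,
                    mean_accuracy=float(rep_scores.mean()) * 100.0,
                    sd_accuracy=sd, n_repeats=repeats, n_folds=k, seed=seed)


def evaluate_combinations(table: pd.DataFrame, combos: list[Combination],
                          specs: list[ClassifierSpec] | None = None,
                          repeats: int = N_REPEATS, k: int = N_FOLDS,
                          seed: int = 0, scale: bool = False) -> list[CVResult]:
    """Run every classifier over every combination."""
    specs = specs if specs is not None else default_classifiers()
    results = []
    rng = np.random.default_rng(seed)
    for combo in combos:
        for spec in specs:
            results.append(repeated_cv(table, combo, spec, repeats=repeats,
                                       k=k, seed=int(rng.integers(2 ** 31)),
                                       scale=scale))
    return results


def rank_combinations(results: list[CVResult]) -> pd.DataFrame:
    """Per-classifier ranking by mean accuracy (desc), SD (asc), name.

    Rows carry a ``score`` column formatted "mean ± sd" with two decimals.
    """
    if not results:
        raise ValueError("no results to rank")
    rows = [{
        "classifier": r.classifier.name,
        "features": ";".join(r.combination.feature_names),
        "mean_accuracy": r.mean_accuracy,
        "sd_accuracy": r.sd_accuracy,
        "score": r.formatted(),
    } for r in results]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["classifier", "mean_accuracy", "sd_accuracy", "features"],
        ascending=[True, False, True, True], kind="mergesort")
    return df.reset_index(drop=True)


def feature_occurrence(results: list[CVResult],
                       accuracy_threshold_pct: float) -> pd.DataFrame:
    """Percent of high-scoring combinations each feature appears in.

    Combinations (deduplicated across classifiers) with mean accuracy
    above the threshold are retained; occurrence(f) = 100 × (#retained
    combinations containing f) / (#retained combinations), sorted
    descending.
    """
    if not results:
        raise ValueError("no results given")
    retained = {r.combination.feature_names
                for r in results if r.mean_accuracy > accuracy_threshold_pct}
    if not retained:
        return pd.DataFrame(columns=["feature", "occurrence_pct"])
    counts: dict[str, int] = {}
    for combo in retained:
        for f in combo:
            counts[f] = counts.get(f, 0) + 1
    df = pd.DataFrame(
        [{"feature": f, "occurrence_pct": 100.0 * c / len(retained)}
         for f, c in counts.items()])
    return (df.sort_values(by=["occurrence_pct", "feature"],
                           ascending=[False, True], kind="mergesort")
            .reset_index(drop=True))


@dataclass
class PCABaselineResult:
    variance_table: pd.DataFrame  # explained + cumulative variance, percent
    results: list[CVResult]
    best_per_classifier: pd.DataFrame


def pca_baseline(table: pd.DataFrame, n_components: int = 10,
                 sizes=(2, 3, 4, 5), repeats: int = N_REPEATS,
                 k: int = N_FOLDS, seed: int = 0,
                 specs: list[ClassifierSpec] | None = None,
                 label_col: str = "label",
                 feature_cols: list[str] | None = None) -> PCABaselineResult:
    """PCA comparison arm: z-score features, evaluate PC-score combinations.

    Columns are standardized (mean 0, SD 1); principal components of the
    standardized matrix give the explained/cumulative variance table, and
    combinations of the first ``n_components`` PC scores are pushed
    through the same repeated-CV machinery for every classifier.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in (label_col, "subject_id")]
    x = table[feature_cols].to_numpy(dtype=float)
    keep = np.std(x, axis=0) > 0
    x = x[:, keep]
    if x.shape[1] < n_components:
        raise ValueError("fewer non-degenerate features than components")
    if x.shape[0] < n_components:
        raise ValueError("fewer subjects than components")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    pca = PCA()
    scores = pca.fit_transform(z)
    expl = pca.explained_variance_ratio_ * 100.0
    variance_table = pd.DataFrame({
        "component": np.arange(1, expl.size + 1),
        "explained_variance_pct": expl,
        "cumulative_variance_pct": np.cumsum(expl),
    })
    pc_names = [f"PC{i + 1}" for i in range(n_components)]
    pc_table = pd.DataFrame(scores[:, :n_components], columns=pc_names)
    pc_table[label_col] = table[label_col].to_numpy()
    combos = [Combination(tuple(c), 0.0)
              for size in sizes
              for c in itertools.combinations(pc_names, size)]
    results = evaluate_combinations(pc_table, combos, specs=specs,
                                    repeats=repeats, k=k, seed=seed)
    ranked = rank_combinations(results)
    best = (ranked.groupby("classifier", as_index=False).first()
            [["classifier", "features", "mean_accuracy", "sd_accuracy"]])
    return PCABaselineResult(variance_table=variance_table, results=results,
                             best_per_classifier=best)
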