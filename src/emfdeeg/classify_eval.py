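"""Classifier roster, Bayesian tuning and cross-validated evaluation.

Models are specified by family name plus hyperparameters and realized as
scikit-learn estimators.  Evaluation is stratified k-fold CV (optionally
grouped by subject) with per-fold confusion counts, pooled
accuracy/sensitivity/specificity/precision/F-score in percent, ROC/AUC
from pooled out-of-fold scores, a label-permutation test and a
learning-curve analysis.  The positive class is ``task`` throughout, so
sensitivity tracks task detection.

Fold-internal discipline: min-max normalization (and, if enabled,
feature reduction) is fitted on the training folds only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import BaggingClassifier, GradientBoostingClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KernelDensity, KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .entropy_features import META_COLUMNS, FeatureReducer, MinMaxNormalizer

POSITIVE_LABEL = "task"

FAMILIES = ("boosted_trees", "bagged_trees", "subspace_knn",
            "subspace_discriminant", "svm", "knn", "naive_bayes",
            "discriminant", "logistic", "tree")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus hyperparameters and a seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")


class KDENaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with a per-class Gaussian kernel density per feature.

    Fills the role of MATLAB's "kernel naive Bayes": each feature's
    class-conditional density is a 1-D Gaussian KDE (Silverman-like
    bandwidth), combined under the naive independence assumption.
    """

    def __init__(self, bandwidth: str | float = "scott"):
        self.bandwidth = bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.kdes_ = []
        self.priors_ = []
        for cls in self.classes_:
            rows = X[y == cls]
            self.priors_.append(len(rows) / len(X))
            feats = []
            for j in range(X.shape[1]):
                col = rows[:, j:j + 1]
                if isinstance(self.bandwidth, str):
                    sd = col.std()
                    bw = max(1e-6, 1.06 * sd * len(col) ** -0.2) if sd > 0 else 1e-3
                else:
                    bw = self.bandwidth
                feats.append(KernelDensity(bandwidth=bw).fit(col))
            self.kdes_.append(feats)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), len(self.classes_)))
        for c, (feats, prior) in enumerate(zip(self.kdes_, self.priors_)):
            ll = np.log(prior) * np.ones(len(X))
            for j, kde in enumerate(feats):
                ll += kde.score_samples(X[:, j:j + 1])
            out[:, c] = ll
        return out

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def make_estimator(spec: ModelSpec):
    """Realize a :class:`ModelSpec` as a scikit-learn estimator.

    The boosted-trees family uses gradient boosting (the closest analogue
    of a gentle-boost tree ensemble); subspace families are random-feature
    -subspace baggers over their base learner.
    """
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    fam = spec.family
    if fam == "boosted_trees":
        return GradientBoostingClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            learning_rate=hp.get("learning_rate", 0.1),
            max_depth=int(hp.get("max_depth", 3)),
            subsample=hp.get("subsample", 1.0),
            random_state=seed)
    if fam == "bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=hp.get("max_depth"), random_state=seed),
            n_estimators=int(hp.get("n_estimators", 100)),
            random_state=seed)
    if fam == "subspace_knn":
        return BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=int(hp.get("n_neighbors", 5))),
            n_estimators=int(hp.get("n_estimators", 30)),
            max_features=hp.get("max_features", 0.5),
            bootstrap=False, random_state=seed)
    if fam == "subspace_discriminant":
        return BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=int(hp.get("n_estimators", 30)),
            max_features=hp.get("max_features", 0.5),
            bootstrap=False, random_state=seed)
    if fam == "svm":
        kernel = hp.get("kernel", "rbf")
        degree = {"linear": 1, "quadratic": 2, "cubic": 3}.get(kernel, 3)
        sk_kernel = "poly" if kernel in ("quadratic", "cubic") else (
            "linear" if kernel == "linear" else "rbf")
        return SVC(kernel=sk_kernel, degree=degree, C=hp.get("C", 1.0),
                   gamma=hp.get("gamma", "scale"), random_state=seed)
    if fam == "knn":
        return KNeighborsClassifier(
            n_neighbors=int(hp.get("n_neighbors", 5)),
            weights=hp.get("weights", "uniform"),
            metric=hp.get("metric", "minkowski"))
    if fam == "naive_bayes":
        variant = hp.get("variant", "gaussian")
        if variant == "kernel":
            return KDENaiveBayes(bandwidth=hp.get("bandwidth", "scott"))
        return GaussianNB()
    if fam == "discriminant":
        if hp.get("variant", "lda") == "qda":
            return QuadraticDiscriminantAnalysis(reg_param=hp.get("reg_param", 0.0))
        return LinearDiscriminantAnalysis()
    if fam == "logistic":
        return LogisticRegression(C=hp.get("C", 1.0), max_iter=2000,
                                  random_state=seed)
    if fam == "tree":
        return DecisionTreeClassifier(
            max_depth=hp.get("max_depth"),
            min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
            random_state=seed)
    raise ValueError(f"unknown family {fam!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# metrics

def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float | None]:
    """Accuracy/sensitivity/specificity/precision/F-score in percent.

    Undefined ratios (empty denominator) are reported as ``None`` rather
    than zero.
    """
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("all confusion counts are zero")
    ac = 100.0 * (tp + tn) / total
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    sp = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    pr = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    if pr is not None and se is not None and pr + se > 0:
        fs = 2.0 * pr * se / (pr + se)
    else:
        fs = None
    return {"Ac": ac, "Se": se, "Sp": sp, "Pr": pr, "Fs": fs}


def roc_auc(scores: np.ndarray, y: np.ndarray,
            positive=POSITIVE_LABEL) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep and AUC with rank-averaged ties.

    Returns ``(points, auc)`` where points is an array of (fpr, tpr)
    rows from (0,0) to (1,1).  The AUC is the Mann-Whitney statistic
    (probability a positive outscores a negative, ties counted half),
    which equals the trapezoidal area under the tie-grouped curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == positive if y.dtype.kind in "UO" else y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep one point per distinct threshold (last index of each tie group)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class CVResult:
    """Cross-validation outcome with per-fold and pooled statistics."""

    fold_counts: list[tuple[int, int, int, int]]  # (tp, fn, tn, fp) per fold
    fold_metrics: list[dict]
    pooled: dict
    fold_accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    ci95: tuple[float, float]
    roc_points: np.ndarray
    auc: float
    seed: int
    n_folds: int
    fold_assignment: np.ndarray
    model_spec: ModelSpec


def _scores_of(model, X) -> np.ndarray:
    """Continuous score for the positive class."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        pos_idx = list(model.classes_).index(
            POSITIVE_LABEL if POSITIVE_LABEL in model.classes_ else model.classes_[-1])
        return proba[:, pos_idx]
    score = model.decision_function(X)
    # decision_function is oriented toward classes_[-1]
    if list(model.classes_)[-1] != POSITIVE_LABEL and POSITIVE_LABEL in model.classes_:
        score = -score
    return score


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.drop(columns=[c for c in META_COLUMNS if c in X.columns])
    return pd.DataFrame(np.asarray(X, dtype=float))


def stratified_kfold_cv(spec: ModelSpec, X, y, k: int = 10,
                        seed: int = 0, groups=None,
                        normalize: bool = True,
                        reduce: FeatureReducer | None = None) -> CVResult:
    """Stratified (optionally subject-grouped) k-fold cross-validation.

    Every row is scored exactly once out of fold.  Normalization and, if
    given, feature reduction are fitted inside each training fold only.
    Fold accuracies feed the mean/SD and the t-based 95% confidence
    interval; confusion counts are pooled across folds for the headline
    metric table; ROC/AUC come from the pooled out-of-fold scores.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    Xf = _as_frame(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the minority class count {counts.min()}")
    if groups is not None:
        groups = np.asarray(groups)
        if len(np.unique(groups)) < k:
            raise ValueError("need at least k distinct groups for grouped CV")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xf, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xf, y)

    pos = (y == POSITIVE_LABEL) if y.dtype.kind in "UO" else (y == 1)
    fold_assignment = np.full(len(y), -1, dtype=int)
    fold_counts, fold_metrics, fold_acc = [], [], []
    oof_scores = np.full(len(y), np.nan)
    for fold, (tr, te) in enumerate(split_iter):
        fold_assignment[te] = fold
        X_tr, X_te = Xf.iloc[tr], Xf.iloc[te]
        if normalize:
            norm = MinMaxNormalizer().fit(X_tr)
            X_tr, X_te = norm.transform(X_tr), norm.transform(X_te)
        if reduce is not None:
            red = clone_reducer(reduce).fit(X_tr)
            X_tr, X_te = red.transform(X_tr), red.transform(X_te)
        model = clone(make_estimator(spec))
        model.fit(X_tr.to_numpy(dtype=float), y[tr])
        pred = model.predict(X_te.to_numpy(dtype=float))
        oof_scores[te] = _scores_of(model, X_te.to_numpy(dtype=float))
        pred_pos = (pred == POSITIVE_LABEL) if y.dtype.kind in "UO" else (pred == 1)
        te_pos = pos[te]
        tp = int(np.sum(pred_pos & te_pos))
        fn = int(np.sum(~pred_pos & te_pos))
        tn = int(np.sum(~pred_pos & ~te_pos))
        fp = int(np.sum(pred_pos & ~te_pos))
        fold_counts.append((tp, fn, tn, fp))
        fold_metrics.append(confusion_metrics(tp, fn, tn, fp))
        fold_acc.append(100.0 * (tp + tn) / len(te))

    tp, fn, tn, fp = (sum(c[i] for c in fold_counts) for i in range(4))
    pooled = confusion_metrics(tp, fn, tn, fp)
    fold_acc = np.asarray(fold_acc)
    mean_acc = float(fold_acc.mean())
    sd_acc = float(fold_acc.std(ddof=1)) if k > 1 else 0.0
    half = sstats.t.ppf(0.975, k - 1) * sd_acc / math.sqrt(k)
    roc_points, auc = roc_auc(oof_scores, y)
    return CVResult(fold_counts, fold_metrics, pooled, fold_acc, mean_acc,
                    sd_acc, (mean_acc - half, mean_acc + half),
                    roc_points, auc, seed, k, fold_assignment, spec)


def clone_reducer(reducer: FeatureReducer) -> FeatureReducer:
    return FeatureReducer(**reducer.get_params())


# ---------------------------------------------------------------------------
# Bayesian optimization

SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    # name -> (kind, low, high) with kind in {int, float, logfloat, cat}
    "boosted_trees": {
        "n_estimators": ("int", 30, 300),
        "learning_rate": ("logfloat", 0.01, 1.0),
        "max_depth": ("int", 1, 6),
        "subsample": ("float", 0.5, 1.0),
    },
    "bagged_trees": {
        "n_estimators": ("int", 20, 300),
        "max_depth": ("int", 2, 20),
    },
    "subspace_knn": {
        "n_neighbors": ("int", 1, 20),
        "n_estimators": ("int", 10, 60),
        "max_features": ("float", 0.2, 0.9),
    },
    "subspace_discriminant": {
        "n_estimators": ("int", 10, 60),
        "max_features": ("float", 0.2, 0.9),
    },
    "svm": {
        "C": ("logfloat", 1e-2, 1e3),
        "gamma": ("logfloat", 1e-4, 10.0),
        "kernel": ("cat", ("linear", "quadratic", "cubic", "rbf")),
    },
    "knn": {
        "n_neighbors": ("int", 1, 30),
        "weights": ("cat", ("uniform", "distance")),
    },
    "naive_bayes": {"variant": ("cat", ("gaussian", "kernel"))},
    "discriminant": {"variant": ("cat", ("lda", "qda")),
                     "reg_param": ("float", 0.0, 1.0)},
    "logistic": {"C": ("logfloat", 1e-3, 1e3)},
    "tree": {"max_depth": ("int", 1, 25),
             "min_samples_leaf": ("int", 1, 20)},
}


def _sample_point(space: dict, rng: np.random.Generator) -> dict:
    point = {}
    for name, sp in space.items():
        kind = sp[0]
        if kind == "int":
            point[name] = int(rng.integers(sp[1], sp[2] + 1))
        elif kind == "float":
            point[name] = float(rng.uniform(sp[1], sp[2]))
        elif kind == "logfloat":
            point[name] = float(np.exp(rng.uniform(np.log(sp[1]), np.log(sp[2]))))
        elif kind == "cat":
            point[name] = sp[1][int(rng.integers(len(sp[1]))) ]
    return point


def _encode(point: dict, space: dict) -> np.ndarray:
    vec = []
    for name, sp in space.items():
        kind = sp[0]
        v = point[name]
        if kind == "int":
            vec.append((v - sp[1]) / max(1, sp[2] - sp[1]))
        elif kind == "float":
            vec.append((v - sp[1]) / (sp[2] - sp[1]))
        elif kind == "logfloat":
            vec.append((np.log(v) - np.log(sp[1])) / (np.log(sp[2]) - np.log(sp[1])))
        elif kind == "cat":
            for option in sp[1]:
                vec.append(1.0 if v == option else 0.0)
    return np.asarray(vec)


def bayesian_optimize(family: str, X, y, budget: int = 30, seed: int = 0,
                      inner_folds: int = 5,
                      n_initial: int = 8) -> tuple[ModelSpec, list[dict]]:
    """Sequential model-based hyperparameter search (GP + expected improvement).

    The objective is mean accuracy of an inner stratified CV.  The first
    ``min(n_initial, budget)`` points are random; subsequent points
    maximize expected improvement of a Matern-5/2 Gaussian-process
    surrogate over 256 random candidates.  Returns the best
    :class:`ModelSpec` and the full evaluation history (each entry has
    ``params`` and ``objective``); the running best of the history is
    monotone non-decreasing by construction.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if family not in SEARCH_SPACES:
        raise ValueError(f"unrecognized family {family!r}")
    space = SEARCH_SPACES[family]
    rng = np.random.default_rng(seed)

    def objective(params: dict) -> float:
        spec = ModelSpec(family, params, seed=seed)
        res = stratified_kfold_cv(spec, X, y, k=inner_folds, seed=seed)
        return res.mean_accuracy

    history: list[dict] = []
    encoded: list[np.ndarray] = []
    values: list[float] = []
    for it in range(budget):
        if it < min(n_initial, budget) or len(set(values)) < 2:
            point = _sample_point(space, rng)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=0.3) + 1e-6 * Matern(nu=2.5),
                alpha=1e-4, normalize_y=True, random_state=seed)
            gp.fit(np.vstack(encoded), np.asarray(values))
            cands = [_sample_point(space, rng) for _ in range(256)]
            enc = np.vstack([_encode(c, space) for c in cands])
            mu, sd = gp.predict(enc, return_std=True)
            best = max(values)
            sd = np.maximum(sd, 1e-9)
            z = (mu - best) / sd
            ei = (mu - best) * sstats.norm.cdf(z) + sd * sstats.norm.pdf(z)
            point = cands[int(np.argmax(ei))]
        val = objective(point)
        history.append({"params": point, "objective": val})
        encoded.append(_encode(point, space))
        values.append(val)
    best_idx = int(np.argmax(values))
    best_spec = ModelSpec(family, history[best_idx]["params"], seed=seed)
    return best_spec, history


# ---------------------------------------------------------------------------
# permutation test & learning curve

@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float


def permutation_test(spec: ModelSpec, X, y, n_perm: int = 100,
                     k: int = 10, seed: int = 0) -> PermutationResult:
    """Label-permutation test on mean CV accuracy.

    Labels are shuffled wholesale each iteration and the full CV is rerun;
    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` (add-one rule, so
    p is never zero).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y)
    observed = stratified_kfold_cv(spec, X, y, k=k, seed=seed).mean_accuracy
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        permuted[i] = stratified_kfold_cv(spec, X, y_perm, k=k,
                                          seed=seed + 1 + i).mean_accuracy
    p = (1 + int(np.sum(permuted >= observed))) / (n_perm + 1)
    return PermutationResult(observed, permuted, p)


def learning_curve(spec: ModelSpec, X, y, fractions=(0.1, 0.25, 0.5, 0.75, 1.0),
                   k: int = 5, seed: int = 0, repeats: int = 3) -> pd.DataFrame:
    """Accuracy versus training-set proportion.

    For each fraction the training folds are stratified-subsampled and
    the model evaluated both on that subsample (train accuracy) and on
    the untouched test fold (validation accuracy), averaged over folds
    and repeats.
    """
    fractions = list(fractions)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    Xf = _as_frame(X)
    y = np.asarray(y)
    rows = []
    for frac in fractions:
        train_accs, val_accs = [], []
        for rep in range(repeats):
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=seed + rep)
            for tr, te in splitter.split(Xf, y):
                rng = np.random.default_rng(seed + rep)
                sub = _stratified_subsample(y[tr], frac, rng)
                tr_sub = tr[sub]
                if len(np.unique(y[tr_sub])) < 2:
                    raise ValueError(
                        f"fraction {frac} yields a single-class training subsample")
                norm = MinMaxNormalizer().fit(Xf.iloc[tr_sub])
                X_tr = norm.transform(Xf.iloc[tr_sub]).to_numpy(dtype=float)
                X_te = norm.transform(Xf.iloc[te]).to_numpy(dtype=float)
                model = clone(make_estimator(spec))
                model.fit(X_tr, y[tr_sub])
                train_accs.append(100.0 * np.mean(model.predict(X_tr) == y[tr_sub]))
                val_accs.append(100.0 * np.mean(model.predict(X_te) == y[te]))
        rows.append({"fraction": frac,
                     "train_accuracy": float(np.mean(train_accs)),
                     "validation_accuracy": float(np.mean(val_accs))})
    return pd.DataFrame(rows)


def _stratified_subsample(y: np.ndarray, frac: float,
                          rng: np.random.Generator) -> np.ndarray:
    idx = []
    for cls in np.unique(y):
        cls_idx = np.nonzero(y == cls)[0]
        n_take = max(1, int(round(frac * len(cls_idx))))
        idx.append(rng.choice(cls_idx, size=n_take, replace=False))
    return np.sort(np.concatenate(idx))
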