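"""Multivariate classification of contractile function: eight methods,
nested leave-one-out evaluation, ROC convex hull and factor importance.

The classification task is case (MI) versus control (healthy) from a
handful of biomechanical features.  Positive labels are MI hearts: a true
positive is a correctly identified MI heart.  Out-of-sample predictions
come from an outer leave-one-out loop; methods with regularization
parameters tune them with an *inner* leave-one-out loop restricted to the
outer training set, so evaluation data never influence tuning.  The
Bayesian Gaussian-process classifier instead sets its hyperparameters by
maximizing the marginal likelihood of the outer training data.

The method portfolio: univariate logistic regression (one model per
feature), multivariate logistic regression, k-nearest neighbours, linear
discriminant analysis, L1-regularized (lasso) logistic regression,
boosted entropy-split decision trees (a stand-in for the C5.0 family),
random forests, and a Gaussian process with automatic relevance
determination (GP-ARD, one squared-exponential length scale per feature).

Sensitivity/specificity points of the whole portfolio are summarized by
the upper convex hull in ROC space and its area (AUROC); per-method
factor-importance scores are fused into a cumulative rank (0 .. p-1 per
method, summed across methods).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

__all__ = ["METHODS", "ClassifierSpec", "EvalResult", "default_specs",
           "nested_loocv", "metrics", "roc_hull", "importance",
           "cumulative_rank", "run_study", "loocv_splits"]

METHODS = ("univariate_lr", "multivariate_lr", "knn", "lda", "lasso_lr",
           "boosted_entropy_tree", "random_forest", "gp_ard")

IMPORTANCE_METHODS = ("lasso_lr", "gp_ard", "boosted_entropy_tree", "random_forest")

_STANDARDIZED = {"univariate_lr", "multivariate_lr", "knn", "lasso_lr", "gp_ard"}

_LASSO_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class ClassifierSpec:
    """A method plus its hyperparameter grid (empty grid = no tuning)."""

    method: str
    grid: tuple = ()
    grid_param: str = ""

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def default_specs() -> list:
    """The eight-method portfolio with its default grids.

    KNN favours small k; lasso tunes its L1 penalty.  The boosted tree
    uses a fixed 10 rounds and the forest 50 trees (single-point grids):
    with tens of subjects these are already saturated and leaving them
    untuned keeps the inner loop cheap.
    """
    return [
        ClassifierSpec("univariate_lr"),
        ClassifierSpec("multivariate_lr"),
        ClassifierSpec("knn", grid=(1, 3, 5, 7), grid_param="n_neighbors"),
        ClassifierSpec("lda"),
        ClassifierSpec("lasso_lr", grid=_LASSO_C_GRID, grid_param="C"),
        ClassifierSpec("boosted_entropy_tree"),
        ClassifierSpec("random_forest"),
        ClassifierSpec("gp_ard"),
    ]


def _make_estimator(method: str, hp=None, seed: int = 0, n_features: int = 1):
    if method in ("multivariate_lr", "univariate_lr"):
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    elif method == "knn":
        est = KNeighborsClassifier(n_neighbors=int(hp or 3))
    elif method == "lda":
        est = LinearDiscriminantAnalysis()
    elif method == "lasso_lr":
        est = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                 C=float(hp or 1.0), max_iter=2000)
    elif method == "boosted_entropy_tree":
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(criterion="entropy", max_depth=2,
                                             random_state=seed),
            n_estimators=int(hp or 10), random_state=seed)
    elif method == "random_forest":
        est = RandomForestClassifier(n_estimators=int(hp or 50),
                                     max_features="sqrt", random_state=seed)
    elif method == "gp_ard":
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            length_scale=np.ones(n_features), length_scale_bounds=(1e-2, 1e3))
        est = GaussianProcessClassifier(kernel=kernel, random_state=seed,
                                        n_restarts_optimizer=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    if method in _STANDARDIZED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class EvalResult:
    """Outcome of a nested-LOOCV evaluation of one classifier."""

    method: str
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    predictions: np.ndarray = field(default_factory=lambda: np.array([]))
    probabilities: np.ndarray = field(default_factory=lambda: np.array([]))
    chosen_hp: list = field(default_factory=list)
    skipped_folds: list = field(default_factory=list)
    feature: str | None = None      # set for univariate models

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def scores(self) -> dict:
        return metrics(self.tp, self.tn, self.fp, self.fn)

    def roc_point(self):
        s = self.scores()
        return (1.0 - s["specificity"], s["sensitivity"])


def metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), error (FP+FN)/n.

    Zero denominators yield NaN for the affected quantity together with an
    ``undefined`` flag rather than an exception.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    n = tp + tn + fp + fn
    sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    err = (fp + fn) / n if n > 0 else np.nan
    return {"sensitivity": sens, "specificity": spec, "error": err,
            "undefined": not np.isfinite(sens) or not np.isfinite(spec)
            or not np.isfinite(err)}


def loocv_splits(n: int):
    """Leave-one-out folds over range(n): (train_indices, test_index) pairs,
    in test-index order n-1 .. 0 (train on the rest)."""
    idx = np.arange(n)
    return [(idx[idx != i], i) for i in range(n - 1, -1, -1)]


def _fold_standardize(X, j):
    """Training rows and held-out row of inner fold j, standardized with the
    training-fold statistics (the same convention StandardScaler applies)."""
    mask = np.ones(len(X), bool)
    mask[j] = False
    Xt = X[mask]
    mu = Xt.mean(axis=0)
    sd = Xt.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xt - mu) / sd, (X[j] - mu) / sd, mask


def _inner_tune(spec: ClassifierSpec, X, y, seed: int) -> object:
    """Pick the grid value minimizing inner-LOOCV error (ties: first in grid).

    KNN and lasso use streamlined inner loops equivalent to refitting the
    full standardize+fit pipeline per fold.
    """
    if spec.method == "knn":
        return _tune_knn(X, y, spec.grid)
    if spec.method == "lasso_lr":
        return _tune_lasso(X, y, spec.grid)
    best_hp, best_err = spec.grid[0], np.inf
    for hp in spec.grid:
        wrong = 0
        for tr, te in loocv_splits(len(y)):
            if len(np.unique(y[tr])) < 2:
                continue
            est = _make_estimator(spec.method, hp, seed, X.shape[1])
            est.fit(X[tr], y[tr])
            wrong += int(est.predict(X[te:te + 1])[0] != y[te])
        err = wrong / len(y)
        if err < best_err - 1e-12:
            best_hp, best_err = hp, err
    return best_hp


def _tune_knn(X, y, ks):
    """Inner-LOOCV error for every k in one pass over the folds."""
    m = len(y)
    errs = {k: 0 for k in ks}
    for j in range(m):
        Z, zj, mask = _fold_standardize(X, j)
        yt = y[mask]
        if len(np.unique(yt)) < 2:
            continue
        d = np.einsum("ij,ij->i", Z - zj, Z - zj)
        order = np.argsort(d, kind="stable")
        for k in ks:
            vote = yt[order[:min(k, m - 1)]].mean()
            if int(vote > 0.5) != y[j]:
                errs[k] += 1
    return min(ks, key=lambda k: (errs[k], list(ks).index(k)))


def _tune_lasso(X, y, Cs):
    """Inner-LOOCV error per L1 penalty with a single reusable estimator."""
    m = len(y)
    est = LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=2000)
    folds = [_fold_standardize(X, j) for j in range(m)]
    best_hp, best_err = Cs[0], np.inf
    with sklearn.config_context(assume_finite=True):
        for C in Cs:
            est.C = float(C)
            wrong = 0
            for j, (Z, zj, mask) in enumerate(folds):
                yt = y[mask]
                if len(np.unique(yt)) < 2:
                    continue
                est.fit(Z, yt)
                wrong += int(est.predict(zj[None, :])[0] != y[j])
            err = wrong / m
            if err < best_err - 1e-12:
                best_hp, best_err = C, err
    return best_hp


def nested_loocv(spec: ClassifierSpec, table: pd.DataFrame, seed: int = 0,
                 columns=None, threshold: float = 0.5) -> EvalResult:
    """Nested leave-one-out evaluation of one classifier spec.

    ``table`` holds a ``label`` column ('healthy'/'mi') plus feature
    columns (restrictable with ``columns``).  The outer loop leaves each
    subject out in turn; methods with a grid re-tune on every outer
    training set via an inner leave-one-out loop.  Probabilities above
    ``threshold`` predict MI.
    """
    cols = [c for c in (columns or table.columns) if c not in ("label", "subject_id")]
    X = table[cols].to_numpy(float)
    y = (table["label"].to_numpy() == "mi").astype(int)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    res = EvalResult(method=spec.method,
                     predictions=np.full(n, -1),
                     probabilities=np.full(n, np.nan))
    ss = np.random.SeedSequence([seed, zlib.crc32(spec.method.encode()) % (2**31)])
    fold_seeds = ss.generate_state(n)
    for tr, i in loocv_splits(n):
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"fold {i}: a class is absent from the training set; skipped")
            res.skipped_folds.append(i)
            continue
        fseed = int(fold_seeds[i] % (2**31))
        hp = None
        if len(spec.grid) > 1:
            hp = _inner_tune(spec, X[tr], y[tr], fseed)
        elif len(spec.grid) == 1:
            hp = spec.grid[0]
        res.chosen_hp.append(hp)
        est = _make_estimator(spec.method, hp, fseed, X.shape[1])
        est.fit(X[tr], y[tr])
        proba = float(est.predict_proba(X[i:i + 1])[0, list(est.classes_).index(1)])
        pred = int(proba > threshold)
        res.probabilities[i] = proba
        res.predictions[i] = pred
        if pred == 1 and y[i] == 1:
            res.tp += 1
        elif pred == 0 and y[i] == 0:
            res.tn += 1
        elif pred == 1 and y[i] == 0:
            res.fp += 1
        else:
            res.fn += 1
    return res


def roc_hull(points) -> dict:
    """Upper convex hull of (1-specificity, sensitivity) points in ROC space.

    Anchors (0,0) and (1,1) are always included; the area under the hull
    (trapezoidal rule) is the ensemble AUROC.  With no informative points
    the hull is the diagonal and the AUROC 0.5.
    """
    pts = [(float(x), float(y)) for x, y in points
           if np.isfinite(x) and np.isfinite(y)]
    if any(not (0 <= x <= 1 and 0 <= y <= 1) for x, y in pts):
        raise ValueError("ROC points must lie in the unit square")
    pts = sorted(set(pts) | {(0.0, 0.0), (1.0, 1.0)})
    hull = []
    for p in pts:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
            if cross >= 0:     # a is on or below the chord o-p: not on the upper hull
                hull.pop()
            else:
                break
        hull.append(p)
    xs = np.array([p[0] for p in hull])
    ys = np.array([p[1] for p in hull])
    auroc = float(np.trapezoid(ys, xs))
    return {"vertices": hull, "auroc": auroc}


def importance(method: str, table: pd.DataFrame, seed: int = 0,
               columns=None) -> pd.Series:
    """Per-feature importance score for one of the four scoring methods.

    lasso: mean absolute standardized regression coefficient over
    leave-one-out refits; GP-ARD: inverted, normalized kernel length
    scales; boosted tree: fraction of boosting rounds using the feature in
    any split; random forest: mean decrease in cross-validated accuracy
    when the feature is excluded from training.
    """
    if method not in IMPORTANCE_METHODS:
        raise ValueError(f"method {method!r} provides no importance measure")
    cols = [c for c in (columns or table.columns) if c not in ("label", "subject_id")]
    X = table[cols].to_numpy(float)
    y = (table["label"].to_numpy() == "mi").astype(int)

    if method == "lasso_lr":
        C = _inner_tune(ClassifierSpec("lasso_lr", _LASSO_C_GRID, "C"), X, y, seed)
        coefs = []
        for tr, _ in loocv_splits(len(y)):
            est = _make_estimator("lasso_lr", C, seed, X.shape[1])
            est.fit(X[tr], y[tr])
            coefs.append(est.named_steps["clf"].coef_[0])
        scores = np.abs(np.mean(coefs, axis=0))
    elif method == "gp_ard":
        est = _make_estimator("gp_ard", None, seed, X.shape[1])
        est.fit(X, y)
        gpc = est.named_steps["clf"]
        ls = np.atleast_1d(
            gpc.base_estimator_.kernel_.k2.length_scale)
        inv = 1.0 / ls
        scores = inv / inv.sum()
    elif method == "boosted_entropy_tree":
        est = _make_estimator("boosted_entropy_tree", None, seed, X.shape[1])
        est.fit(X, y)
        used = np.zeros(X.shape[1])
        for tree in est.estimators_:
            feats = set(f for f in tree.tree_.feature if f >= 0)
            for f in feats:
                used[f] += 1
        scores = used / len(est.estimators_)
    else:  # random_forest: exclusion-based accuracy decrease
        cv = StratifiedKFold(n_splits=min(5, np.bincount(y).min()),
                             shuffle=True, random_state=seed)
        def cv_acc(Xs):
            acc = 0
            for tr, te in cv.split(Xs, y):
                est = _make_estimator("random_forest", None, seed, Xs.shape[1])
                est.fit(Xs[tr], y[tr])
                acc += np.sum(est.predict(Xs[te]) == y[te])
            return acc / len(y)
        base = cv_acc(X)
        scores = np.array([base - cv_acc(np.delete(X, j, axis=1))
                           for j in range(X.shape[1])])
    return pd.Series(scores, index=cols, name=method)


def cumulative_rank(tables: dict) -> pd.DataFrame:
    """Fuse per-method importance scores into cumulative ranks.

    Each method's features are ranked in ascending order of importance
    (0 .. p-1, ties broken by stable input order); ranks are summed across
    methods.  All methods must score the same feature set.
    """
    methods = list(tables)
    feats = list(tables[methods[0]].index)
    for m in methods[1:]:
        if list(tables[m].index) != feats:
            raise ValueError("importance tables must share one feature set")
    out = pd.DataFrame(index=feats)
    for m in methods:
        order = np.argsort(tables[m].to_numpy(), kind="stable")
        ranks = np.empty(len(feats), int)
        ranks[order] = np.arange(len(feats))
        out[m] = ranks
    out["accumulated"] = out[methods].sum(axis=1)
    return out


def permutation_null_auroc(table: pd.DataFrame, n_permutations: int = 200,
                           seed: int = 0, n_splits: int = 5,
                           columns=None) -> float:
    """Mean AUROC of multivariate logistic regression under label permutation.

    Class labels are shuffled uniformly at random; held-out probabilities
    from stratified k-fold cross-validation are scored against the permuted
    labels.  The mean over permutations estimates the chance floor (0.5).
    """
    from sklearn.metrics import roc_auc_score
    cols = [c for c in (columns or table.columns) if c not in ("label", "subject_id")]
    X = table[cols].to_numpy(float)
    y = (table["label"].to_numpy() == "mi").astype(int)
    rng = np.random.default_rng(seed)
    aucs = []
    with sklearn.config_context(assume_finite=True):
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            proba = np.empty(len(yp))
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=int(rng.integers(2**31)))
            for tr, te in cv.split(X, yp):
                est = _make_estimator("multivariate_lr", None, 0, X.shape[1])
                est.fit(X[tr], yp[tr])
                proba[te] = est.predict_proba(X[te])[:, list(est.classes_).index(1)]
            aucs.append(roc_auc_score(yp, proba))
    return float(np.mean(aucs))


def run_study(tables: dict, specs=None, seed: int = 0,
              compute_importance: bool = True) -> dict:
    """The full classification study over the datasets in ``tables``.

    For every dataset (name -> feature table): nested-LOOCV metrics for
    all methods (univariate logistic regression contributes one ROC point
    per feature; its reported row is its best feature), the ROC convex
    hull with AUROC, per-method importance and cumulative ranks.  Methods
    are ranked by the sum of misclassification errors over datasets.
    """
    specs = specs or default_specs()
    results: dict = {"datasets": {}, "seed": seed}
    err_sum: dict = {}
    for name, table in tables.items():
        evals, points = [], []
        for spec in specs:
            if spec.method == "univariate_lr":
                feat_cols = [c for c in table.columns
                             if c not in ("label", "subject_id")]
                best = None
                for c in feat_cols:
                    r = nested_loocv(spec, table, seed=seed, columns=[c])
                    r.feature = c
                    points.append(r.roc_point())
                    if best is None or r.scores()["error"] < best.scores()["error"]:
                        best = r
                evals.append(best)
            else:
                r = nested_loocv(spec, table, seed=seed)
                evals.append(r)
                points.append(r.roc_point())
        hull = roc_hull(points)
        if compute_importance:
            imp = {m: importance(m, table, seed=seed) for m in IMPORTANCE_METHODS}
            ranks = cumulative_rank(imp)
        else:
            imp, ranks = {}, None
        rows = []
        for r in evals:
            s = r.scores()
            rows.append({"method": r.method, "feature": r.feature,
                         "error": s["error"], "sensitivity": s["sensitivity"],
                         "specificity": s["specificity"],
                         "tp": r.tp, "tn": r.tn, "fp": r.fp, "fn": r.fn})
            err_sum[r.method] = err_sum.get(r.method, 0.0) + s["error"]
        results["datasets"][name] = {
            "metrics": pd.DataFrame(rows), "roc_points": points,
            "hull": hull, "auroc": hull["auroc"],
            "importance": pd.DataFrame(imp), "ranks": ranks,
        }
    order = sorted(err_sum, key=lambda m: err_sum[m])
    results["method_ranking"] = pd.DataFrame(
        {"method": order, "error_sum": [err_sum[m] for m in order],
         "rank": np.arange(1, len(order) + 1)})
    return results
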