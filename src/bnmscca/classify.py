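"""Patient-vs-control classification benchmark for the selected biomarkers.

Six feature-selection strategies (none, two-sample t-test, and top-weight
selection from each of the four association solvers) feed a linear SVM
evaluated by repeated stratified 10-fold cross-validation, reporting
accuracy, sensitivity (positive = patient class), specificity and AUC on
the percent scale.  Feature selection is refit inside each training fold by
default so no held-out subject influences the selected columns; a
``mode="global"`` variant selects once on the full sample for comparability
with analyses that reuse association-stage weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .biomarkers import top_k
from .exceptions import ValidationError
from .model_selection import make_estimator, _fit

__all__ = [
    "ClassificationReport",
    "confusion_metrics",
    "ttest_select",
    "tune_ttest_threshold",
    "cca_select",
    "evaluate",
    "benchmark",
    "STRATEGIES",
]

STRATEGIES = ("original", "ttest", "scca", "sccar", "mscca", "bn_mscca")


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """ACC/SEN/SPE (percent) from confusion-matrix counts."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    return {
        "acc": 100.0 * (tp + tn) / total,
        "sen": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "spe": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
    }


def ttest_select(features, labels, p_threshold: float) -> np.ndarray:
    """Indices of features whose equal-variance two-sample t-test p-value is
    below the threshold (patients vs controls)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    g0, g1 = X[y == 0], X[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValidationError("each class needs at least 2 samples")
    with warnings.catch_warnings():
        # constant columns produce a harmless precision warning; they get p=1
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(g1, g0, axis=0, equal_var=True)
    p = np.where(np.isfinite(p), p, 1.0)
    return np.flatnonzero(p < p_threshold)


def tune_ttest_threshold(features, labels, thresholds=None, folds=3, seed=0,
                         C=1.0) -> float:
    """Pick the p-value threshold maximizing inner-CV accuracy (thresholds
    default to 0.01..0.10 in steps of 0.01)."""
    thresholds = (
        np.round(np.arange(0.01, 0.101, 0.01), 2) if thresholds is None else thresholds
    )
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
    best, best_acc = float(thresholds[0]), -np.inf
    for th in thresholds:
        accs = []
        for tr, va in cv.split(X, y):
            sel = ttest_select(X[tr], y[tr], th)
            if sel.size == 0:
                accs.append(0.0)
                continue
            clf = _make_pipeline(C).fit(X[np.ix_(tr, sel)], y[tr])
            accs.append(clf.score(X[np.ix_(va, sel)], y[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best = acc, float(th)
    return best


def cca_select(method, X, Y, Z, groups=None, params=None, k=10, **est_kwargs):
    """Top-k feature indices per modality by |canonical weight| from one
    solver fit on the given (training) data."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if params is None:
        params = (1.0, 1.0, 1.0) if method in ("bn_mscca", "mscca") else (0.3, 0.3)
    est = make_estimator(method, params, groups, **est_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _fit(est, method, X, Y, np.asarray(Z, float).ravel(), np.arange(X.shape[0]))
    labels_x = [f"{j}" for j in range(X.shape[1])]
    labels_y = [f"{j}" for j in range(Y.shape[1])]
    ix = top_k(est.u_, labels_x, k=min(k, X.shape[1]))["roi"].astype(int).to_numpy()
    iy = top_k(est.v_, labels_y, k=min(k, Y.shape[1]))["roi"].astype(int).to_numpy()
    return np.sort(ix), np.sort(iy)


@dataclass
class ClassificationReport:
    """Fold-level ACC/SEN/SPE/AUC (percent) plus mean +/- sd summaries."""

    acc: np.ndarray
    sen: np.ndarray
    spe: np.ndarray
    auc: np.ndarray
    folds: int = 10
    repeats: int = 10
    seed: int | None = None
    n_selected: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name in ("acc", "sen", "spe", "auc"):
            a = getattr(self, name)
            rows[name.upper()] = {
                "mean": float(np.nanmean(a)),
                "sd": float(np.nanstd(a, ddof=1)),
            }
        return pd.DataFrame(rows).T


def _make_pipeline(C):
    from sklearn.pipeline import make_pipeline

    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))


def evaluate(features, labels, folds=10, repeats=10, seed=0, selector=None,
             C=1.0) -> ClassificationReport:
    """Repeated stratified K-fold linear-SVM evaluation.

    ``selector(train_features, train_labels) -> column indices`` is called
    once per training fold (never sees held-out rows); ``None`` keeps every
    column.  AUC comes from the SVM decision scores.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValidationError("labels must be binary 0/1 with both classes present")
    accs, sens, spes, aucs, nsel = [], [], [], [], []
    for rep in range(repeats):
        cv = StratifiedKFold(folds, shuffle=True, random_state=seed + rep)
        for tr, te in cv.split(X, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                raise ValidationError("stratification failure: single-class fold")
            cols = np.arange(X.shape[1]) if selector is None else np.asarray(
                selector(X[tr], y[tr]), dtype=int
            )
            if cols.size == 0:
                cols = np.arange(X.shape[1])
            nsel.append(cols.size)
            clf = _make_pipeline(C).fit(X[np.ix_(tr, cols)], y[tr])
            pred = clf.predict(X[np.ix_(te, cols)])
            scores = clf.decision_function(X[np.ix_(te, cols)])
            tp = int(np.sum((pred == 1) & (y[te] == 1)))
            tn = int(np.sum((pred == 0) & (y[te] == 0)))
            fp = int(np.sum((pred == 1) & (y[te] == 0)))
            fn = int(np.sum((pred == 0) & (y[te] == 1)))
            m = confusion_metrics(tp, tn, fp, fn)
            accs.append(m["acc"])
            sens.append(m["sen"])
            spes.append(m["spe"])
            aucs.append(100.0 * roc_auc_score(y[te], scores))
    return ClassificationReport(
        np.array(accs), np.array(sens), np.array(spes), np.array(aucs),
        folds, repeats, seed, nsel,
    )


def _strategy_selector(strategy, p, q, groups, params, k, seed):
    """Build the per-fold column selector for one strategy on the
    concatenated [X | Y] feature matrix (p columns of X first)."""
    if strategy == "original":
        return None
    if strategy == "ttest":
        def sel(F, y):
            th = tune_ttest_threshold(F, y, seed=seed)
            return ttest_select(F, y, th)
        return sel
    if strategy in ("scca", "sccar", "mscca", "bn_mscca"):
        def sel(F, y):
            ix, iy = cca_select(
                strategy, F[:, :p], F[:, p:p + q], y, groups, params, k=k
            )
            return np.concatenate([ix, p + iy])
        return sel
    raise ValidationError(f"unknown strategy {strategy!r}")


def benchmark(X, Y, Z, groups=None, strategies=STRATEGIES, folds=10, repeats=10,
              seed=0, k=10, params=None, mode="nested", C=1.0) -> dict:
    """Run the full strategy comparison; returns strategy -> report.

    ``mode="nested"`` refits feature selection inside every training fold
    (leakage-free, the default); ``mode="global"`` selects once on all data
    before the classification CV.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    y = np.asarray(Z, float).ravel()
    F = np.hstack([X, Y])
    p, q = X.shape[1], Y.shape[1]
    out = {}
    for strategy in strategies:
        if mode == "nested" or strategy == "original":
            sel = _strategy_selector(strategy, p, q, groups, params, k, seed)
        elif mode == "global":
            if strategy == "ttest":
                th = tune_ttest_threshold(F, y, seed=seed)
                fixed = ttest_select(F, y, th)
            else:
                ix, iy = cca_select(strategy, X, Y, y, groups, params, k=k)
                fixed = np.concatenate([ix, p + iy])
            sel = (lambda cols: (lambda F_, y_: cols))(fixed)
        else:
            raise ValidationError(f"unknown mode {mode!r}")
        out[strategy] = evaluate(F, y, folds, repeats, seed, selector=sel, C=C)
    return out
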