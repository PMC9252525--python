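"""Model selection and evaluation protocol for the association solvers.

Nested cross-validation: an outer stratified 5-fold split (repeated, by
default 5 times) estimates train/test canonical correlation coefficients
(CCCs); inside every outer-training set an inner 5-fold grid search picks
the hyperparameters minimizing the mean absolute gap between training and
validation CCC — a stability criterion that favors settings that
generalize.  Weights from all outer fits are sign-aligned (each solver
already canonicalizes the sign of its dominant entry) and averaged.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ValidationError
from .solvers import BNMSCCA, MSCCA, SCCA, SCCAR

logger = logging.getLogger(__name__)

__all__ = [
    "LAMBDA_GRID",
    "SCCA_GRID",
    "CVSearchResult",
    "default_grid",
    "make_estimator",
    "grid_search",
    "repeated_cv",
]

# canonical tuning grids: lambdas over five decades for the three-view
# solvers, fractional soft-threshold levels 0.01:0.05:0.5 for SCCA/SCCAR
LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
SCCA_GRID = tuple(np.round(np.arange(0.01, 0.5, 0.05), 2))

_THREE_VIEW = {"bn_mscca", "mscca"}
_TWO_VIEW = {"scca", "sccar"}


def default_grid(method: str):
    """All hyperparameter tuples searched for a solver tag (125 triples for
    the three-view solvers, 100 pairs for SCCA/SCCAR)."""
    if method in _THREE_VIEW:
        return list(itertools.product(LAMBDA_GRID, LAMBDA_GRID, LAMBDA_GRID))
    if method in _TWO_VIEW:
        return list(itertools.product(SCCA_GRID, SCCA_GRID))
    raise ValidationError(f"unknown method {method!r}")


def make_estimator(method: str, params, groups=None, **kwargs):
    """Instantiate a solver from its tag and a grid point."""
    params = tuple(params)
    if method == "bn_mscca":
        if groups is None:
            raise ValidationError("bn_mscca requires a group structure")
        return BNMSCCA(*params, groups=groups, **kwargs)
    if method == "mscca":
        return MSCCA(*params, **kwargs)
    if method == "scca":
        return SCCA(*params, **kwargs)
    if method == "sccar":
        return SCCAR(*params, **kwargs)
    raise ValidationError(f"unknown method {method!r}")


def _fit(est, method, X, Y, Z, rows):
    Xi, Yi = X[rows], Y[rows]
    if method in _THREE_VIEW or method == "sccar":
        est.fit(Xi, Yi, np.asarray(Z, float).ravel()[rows])
    else:
        est.fit(Xi, Yi)
    return est


def _folds(Z, n, folds, seed, stratify):
    if stratify:
        z = np.asarray(Z, float).ravel()
        cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(n), z))
    cv = KFold(folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(n)))


@dataclass
class CVSearchResult:
    """Outcome of a (possibly repeated, nested) grid search."""

    grid: list[tuple]
    per_point: pd.DataFrame          # params, mean train/val CCC, |gap|
    selected: tuple
    per_fold_train_ccc: list[float] = field(default_factory=list)
    per_fold_test_ccc: list[float] = field(default_factory=list)
    averaged_u: np.ndarray | None = None
    averaged_v: np.ndarray | None = None
    averaged_w: np.ndarray | None = None
    selected_per_fold: list[tuple] = field(default_factory=list)
    repeats: int = 1
    seed: int | None = None

    @property
    def train_ccc(self) -> tuple[float, float]:
        a = np.asarray(self.per_fold_train_ccc, float)
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    @property
    def test_ccc(self) -> tuple[float, float]:
        a = np.asarray(self.per_fold_test_ccc, float)
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0


def grid_search(X, Y, Z, groups=None, method="bn_mscca", grid=None, folds=5,
                seed=0, stratify=True, **est_kwargs) -> CVSearchResult:
    """Inner-loop grid search: K-fold CCC on train/validation splits per grid
    point; select the point minimizing mean |CCC_train - CCC_val|, breaking
    ties by lexicographically smallest parameters."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    grid = [tuple(g) for g in (grid if grid is not None else default_grid(method))]
    if not grid:
        raise ValidationError("empty grid")
    n = X.shape[0]
    if n < folds:
        raise ValidationError(f"n={n} < folds={folds}")
    splits = _folds(Z, n, folds, seed, stratify)
    rows = []
    for params in grid:
        tr_cccs, va_cccs = [], []
        ok = True
        for tr, va in splits:
            try:
                est = make_estimator(method, params, groups, **est_kwargs)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _fit(est, method, X, Y, Z, tr)
                tr_cccs.append(est.score(X[tr], Y[tr]))
                va_cccs.append(est.score(X[va], Y[va]))
            except Exception as exc:  # noqa: BLE001 — scored as infinitely bad
                logger.warning("grid point %s failed: %s", params, exc)
                ok = False
                break
        if ok:
            mt, mv = float(np.mean(tr_cccs)), float(np.mean(va_cccs))
            gap = abs(mt - mv)
        else:
            mt = mv = np.nan
            gap = np.inf
        rows.append((*params, mt, mv, gap))
    npar = len(grid[0])
    cols = [f"param{i+1}" for i in range(npar)] + ["ccc_train", "ccc_val", "gap"]
    per_point = pd.DataFrame(rows, columns=cols)
    best_gap = per_point["gap"].min()
    if not np.isfinite(best_gap):
        raise ValidationError("every grid point failed")
    candidates = [g for g, gap in zip(grid, per_point["gap"]) if gap == best_gap]
    selected = min(candidates)
    return CVSearchResult(grid, per_point, selected, repeats=1, seed=seed)


def repeated_cv(X, Y, Z, groups=None, method="bn_mscca", grid=None, folds=5,
                repeats=5, seed=0, stratify=True, inner_folds=None,
                **est_kwargs) -> CVSearchResult:
    """Outer K-fold x repeats evaluation with nested inner grid search.

    Per outer fold: the inner grid search runs on the outer-training set,
    the winning hyperparameters are refit on the outer-training set, and
    CCC is recorded on the outer-train and outer-test splits.  Weights are
    averaged across all outer fits (the solvers' canonical sign convention
    makes the average invariant to fold order).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    z = np.asarray(Z, float).ravel()
    inner_folds = inner_folds or folds
    n = X.shape[0]
    train_cccs, test_cccs, selections = [], [], []
    us, vs, ws = [], [], []
    last_inner = None
    for rep in range(repeats):
        rep_seed = seed + 1000 * rep
        for tr, te in _folds(z, n, folds, rep_seed, stratify):
            inner = grid_search(
                X[tr], Y[tr], z[tr], groups, method, grid,
                folds=inner_folds, seed=rep_seed, stratify=stratify, **est_kwargs
            )
            last_inner = inner
            est = make_estimator(method, inner.selected, groups, **est_kwargs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _fit(est, method, X, Y, z, tr)
            train_cccs.append(est.score(X[tr], Y[tr]))
            test_cccs.append(est.score(X[te], Y[te]))
            selections.append(inner.selected)
            us.append(est.u_)
            vs.append(est.v_)
            if hasattr(est, "w_"):
                ws.append(est.w_)
    result = CVSearchResult(
        grid=last_inner.grid,
        per_point=last_inner.per_point,
        selected=max(set(selections), key=selections.count),
        per_fold_train_ccc=train_cccs,
        per_fold_test_ccc=test_cccs,
        averaged_u=np.mean(us, axis=0),
        averaged_v=np.mean(vs, axis=0),
        averaged_w=np.mean(ws, axis=0) if ws else None,
        selected_per_fold=selections,
        repeats=repeats,
        seed=seed,
    )
    return result
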