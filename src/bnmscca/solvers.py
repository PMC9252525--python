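"""Sparse CCA solvers: SCCA, SCCAR, MSCCA and the brain-network-constrained
three-view model (BN-MSCCA).

BN-MSCCA couples two imaging views X (n x p) and Y (n x q) with a diagnosis
view Z (n x r, r = 1) by maximizing the sum of the three pairwise projected
covariances u'X'Yv + v'Y'Zw + w'Z'Xu under unit-variance constraints
|Xu| = |Yv| = |Zw| = 1, an L1 penalty on each weight vector, and a
group-lasso ("brain network") penalty

    |u|_bn = sum_k |u restricted to network k|_2

that pushes whole networks in or out of the solution.  The unconstrained
objective minimized by the alternating solver is

    -u'X'Yv - v'Y'Zw - w'Z'Xu
    + 1/2 |Xu|^2 + 1/2 |Yv|^2 + 1/2 |Zw|^2
    + l1*a*|u|_bn + l1*(1-a)*|u|_1
    + l2*b*|v|_bn + l2*(1-b)*|v|_1 + l3*|w|_1,

solved by closed-form block updates with iteratively reweighted diagonal
penalty matrices, each block followed (in the default projected mode) by a
rescaling onto its unit-variance constraint.

Estimators follow the scikit-learn API (``fit``/``transform``/``score``,
parameters in ``__init__``, fitted attributes with a trailing underscore);
module-level functions are thin wrappers kept for script use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .datamodel import DiagnosisVector, FeatureMatrix, GroupStructure
from .exceptions import DegenerateWeightError, NumericalError, ValidationError

__all__ = [
    "HyperParams",
    "TriViewWeights",
    "ReweightDiagonals",
    "BNMSCCA",
    "MSCCA",
    "SCCA",
    "SCCAR",
    "soft_threshold",
    "ccc",
    "scale_to_unit",
    "group_norm",
    "objective_bnmscca",
    "build_reweight_diagonals",
    "update_u",
    "update_v",
    "update_w",
    "fit_bn_mscca",
    "fit_mscca",
    "fit_scca",
    "fit_sccar",
]


# ---------------------------------------------------------------------------
# small shared primitives


def soft_threshold(x, delta):
    """S(x, delta) = sign(x) * max(|x| - delta, 0), elementwise."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - float(delta), 0.0)


def scale_to_unit(M, a):
    """Return a / |M a|_2 so that the projected score has unit L2 norm."""
    a = np.asarray(a, dtype=float)
    nrm = np.linalg.norm(np.asarray(M, float) @ a)
    if nrm == 0.0 or not np.isfinite(nrm):
        raise DegenerateWeightError("cannot scale: projection M a is zero")
    return a / nrm


def ccc(X, Y, u, v):
    """Canonical correlation coefficient: Pearson r of the scores Xu, Yv."""
    s = np.asarray(X, float) @ np.asarray(u, float).ravel()
    t = np.asarray(Y, float) @ np.asarray(v, float).ravel()
    if np.std(s) == 0.0 or np.std(t) == 0.0:
        raise NumericalError("zero-variance projection: correlation undefined")
    return float(np.corrcoef(s, t)[0, 1])


def group_norm(x, blocks):
    """Sum over networks of the L2 norm of the within-network sub-vector."""
    x = np.asarray(x, dtype=float)
    return float(sum(math.sqrt(float(x[b] @ x[b])) for b in blocks))


def _as_array(X):
    if isinstance(X, FeatureMatrix):
        return X.values
    if isinstance(X, DiagnosisVector):
        return X.column
    X = np.asarray(X, dtype=float)
    return X.reshape(-1, 1) if X.ndim == 1 else X


def _blocks(groups, d, what):
    if groups is None:
        return None
    if isinstance(groups, GroupStructure):
        blocks = groups.index_blocks
    else:
        blocks = [np.asarray(b, dtype=int) for b in groups]
    cover = np.concatenate(blocks) if blocks else np.array([], int)
    if sorted(cover.tolist()) != list(range(d)):
        raise ValidationError(f"groups must partition the {d} features of {what}")
    return blocks


def _standardize(A, mean=None, std=None):
    A = np.asarray(A, dtype=float)
    if mean is None:
        mean = A.mean(axis=0)
        std = A.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    return (A - mean) / std, mean, std


def _solve_spd(A, b):
    """Solve A x = b for a symmetric positive-definite system, with a tiny
    diagonal jitter fallback; raises with a condition estimate on failure."""
    A = np.asarray(A, float)
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * max(1.0, float(np.trace(A)) / A.shape[0])
    try:
        return np.linalg.solve(A + jitter * np.eye(A.shape[0]), b)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(A)
        raise NumericalError(
            f"singular system after jitter (cond ~ {cond:.3e})"
        ) from exc


# ---------------------------------------------------------------------------
# hyperparameters, diagonals, objective


@dataclass
class HyperParams:
    """Tuning parameters of the three-view solvers.

    lambda1/2/3 weigh the penalties on u, v, w; alpha and beta in [0, 1]
    split lambda1/lambda2 between the network-level and the individual
    (L1) penalty; epsilon smooths the reweighting denominators; tol and
    max_iter control the alternating loop.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    alpha: float = 0.5
    beta: float = 0.5
    epsilon: float = 1e-6
    tol: float = 1e-5
    max_iter: int = 100

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValidationError("lambdas must be non-negative")
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValidationError("alpha and beta must lie in [0, 1]")
        if self.epsilon <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValidationError("epsilon, tol must be > 0 and max_iter >= 1")


@dataclass
class TriViewWeights:
    """Fitted canonical weights (u, v, w) plus convergence metadata."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


@dataclass
class ReweightDiagonals:
    """Diagonals of the reweighting matrices (stored as 1-D arrays).

    d1[j] = 1/(|u_j| + eps); dbar1[j] = 1/(2 |U_k(j)|_2 + eps) with k(j) the
    network of feature j (the "printed" variant; the majorization-consistent
    "mm" variant drops the factor 2); d2/dbar2 analogous for v; d3 for w.
    """

    d1: np.ndarray
    dbar1: np.ndarray | None
    d2: np.ndarray
    dbar2: np.ndarray | None
    d3: np.ndarray


def _group_denoms(x, blocks, epsilon, variant):
    out = np.empty_like(np.asarray(x, float))
    factor = 2.0 if variant == "printed" else 1.0
    for b in blocks:
        xb = x[b]
        out[b] = 1.0 / (factor * math.sqrt(float(xb @ xb)) + epsilon)
    return out


def build_reweight_diagonals(
    u, v, w, groups=None, groups_y=None, epsilon=1e-6, variant="printed"
) -> ReweightDiagonals:
    """Build the diagonal reweighting entries for the current (u, v, w)."""
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    w = np.asarray(w, float).ravel()
    bx = _blocks(groups, u.size, "X") if groups is not None else None
    by = _blocks(groups_y, v.size, "Y") if groups_y is not None else (
        bx if (bx is not None and v.size == u.size) else None
    )
    d1 = 1.0 / (np.abs(u) + epsilon)
    d2 = 1.0 / (np.abs(v) + epsilon)
    d3 = 1.0 / (np.abs(w) + epsilon)
    dbar1 = _group_denoms(u, bx, epsilon, variant) if bx is not None else None
    dbar2 = _group_denoms(v, by, epsilon, variant) if by is not None else None
    return ReweightDiagonals(d1, dbar1, d2, dbar2, d3)


def objective_bnmscca(
    X, Y, Z, u, v, w, groups=None, groups_y=None, hp: HyperParams | None = None
) -> float:
    """Evaluate the unconstrained three-view objective at (u, v, w)."""
    hp = hp or HyperParams()
    X, Y, Z = _as_array(X), _as_array(Y), _as_array(Z)
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    w = np.asarray(w, float).ravel()
    if X.shape[1] != u.size or Y.shape[1] != v.size or Z.shape[1] != w.size:
        raise ValidationError("weight lengths do not match matrix columns")
    Xu, Yv, Zw = X @ u, Y @ v, Z @ w
    val = (
        -float(Xu @ Yv) - float(Yv @ Zw) - float(Zw @ Xu)
        + 0.5 * float(Xu @ Xu) + 0.5 * float(Yv @ Yv) + 0.5 * float(Zw @ Zw)
    )
    bx = _blocks(groups, u.size, "X") if groups is not None else None
    by = _blocks(groups_y, v.size, "Y") if groups_y is not None else (
        bx if (bx is not None and v.size == u.size) else None
    )
    if hp.alpha > 0 and bx is not None:
        val += hp.lambda1 * hp.alpha * group_norm(u, bx)
    val += hp.lambda1 * (1.0 - hp.alpha) * float(np.abs(u).sum())
    if hp.beta > 0 and by is not None:
        val += hp.lambda2 * hp.beta * group_norm(v, by)
    val += hp.lambda2 * (1.0 - hp.beta) * float(np.abs(v).sum())
    val += hp.lambda3 * float(np.abs(w).sum())
    return val


# ---------------------------------------------------------------------------
# block updates


def _constrained_block_solve(G, A, c):
    """Minimize 1/2 a'Aa - a'c subject to a'Ga = 1 (exact block update).

    Classic trust-region-style secular solve: with G = LL', y = L'a, the
    problem becomes min 1/2 y'By - y'b on the unit sphere, solved through
    the eigendecomposition of B and a root find on the multiplier.  Used by
    the ``constraint="constrained"`` mode, whose block-coordinate iteration
    is monotone in the objective.
    """
    import scipy.linalg
    from scipy.optimize import brentq

    G = np.asarray(G, float)
    p = G.shape[0]
    jitter = 1e-12 * max(1.0, float(np.trace(G)) / p)
    L = np.linalg.cholesky(G + jitter * np.eye(p))
    Linv = scipy.linalg.solve_triangular(L, np.eye(p), lower=True)
    B = Linv @ A @ Linv.T
    b = Linv @ c
    lam, Q = np.linalg.eigh((B + B.T) / 2.0)
    d = Q.T @ b

    def norm2(mu):
        return float(np.sum((d / (lam + mu)) ** 2))

    lo = -lam[0]
    if abs(d[0]) < 1e-13 * max(1.0, np.abs(d).max()):
        # hard case: rhs orthogonal to the bottom eigenvector
        rest = lam + lo
        rest[0] = 1.0
        y_part = d / rest
        y_part[0] = 0.0
        s2 = float(y_part @ y_part)
        if s2 <= 1.0:
            y = y_part
            y[0] = np.sqrt(1.0 - s2)
            return Linv.T @ (Q @ y)
    # norm2 decreases from +inf at mu -> lo+ ; bracket the root
    hi = lo + 1.0
    while norm2(hi) > 1.0:
        hi = lo + 2.0 * (hi - lo)
    eps_lo = 1e-12 * max(1.0, abs(lo))
    while norm2(lo + eps_lo) < 1.0:
        eps_lo *= 0.5
        if eps_lo < 1e-300:
            break
    mu = brentq(lambda m: norm2(m) - 1.0, lo + eps_lo, hi, xtol=1e-14)
    y = d / (lam + mu)
    return Linv.T @ (Q @ y)


def _penalized_solve(G, rhs, lam, mix, d, dbar):
    """Solve (G + lam*mix*diag(dbar) + lam*(1-mix)*diag(d)) x = rhs."""
    A = G.copy()
    if lam > 0:
        diag = A.reshape(-1)[:: A.shape[0] + 1]
        if mix > 0 and dbar is not None:
            diag += lam * mix * dbar
        diag += lam * (1.0 - mix) * d
    return _solve_spd(A, rhs)


def update_u(X, Y, Z, v, w, diag: ReweightDiagonals, hp: HyperParams):
    """Closed-form block update of u given (v, w) and the current diagonals."""
    X, Y, Z = _as_array(X), _as_array(Y), _as_array(Z)
    rhs = X.T @ (Y @ np.ravel(v) + Z @ np.ravel(w))
    return _penalized_solve(X.T @ X, rhs, hp.lambda1, hp.alpha, diag.d1, diag.dbar1)


def update_v(X, Y, Z, u, w, diag: ReweightDiagonals, hp: HyperParams):
    X, Y, Z = _as_array(X), _as_array(Y), _as_array(Z)
    rhs = Y.T @ (X @ np.ravel(u) + Z @ np.ravel(w))
    return _penalized_solve(Y.T @ Y, rhs, hp.lambda2, hp.beta, diag.d2, diag.dbar2)


def update_w(X, Y, Z, u, v, diag: ReweightDiagonals, hp: HyperParams):
    X, Y, Z = _as_array(X), _as_array(Y), _as_array(Z)
    rhs = Z.T @ (X @ np.ravel(u) + Y @ np.ravel(v))
    return _penalized_solve(Z.T @ Z, rhs, hp.lambda3, 0.0, diag.d3, None)


def _canonical_sign(u, v, w):
    """Make the largest-|entry| of u positive; the triple flip leaves every
    bilinear term of the objective unchanged."""
    j = int(np.argmax(np.abs(u)))
    if u[j] < 0:
        return -u, -v, -w
    return u, v, w


# ---------------------------------------------------------------------------
# estimators


class BNMSCCA(BaseEstimator):
    """Brain-network-constrained multi-view sparse CCA.

    Alternates closed-form reweighted updates of the canonical weights
    (u, v, w) for views X, Y, Z, each followed by a rescaling onto its
    unit-variance constraint (``constraint="projected"``, the default) or
    left unscaled so the quadratic terms act as soft constraints
    (``constraint="lagrangian"``).

    Parameters
    ----------
    lambda1, lambda2, lambda3 : float
        Penalty weights for u, v, w.
    alpha, beta : float in [0, 1]
        Split of lambda1 (resp. lambda2) between the network-level group
        penalty and the individual L1 penalty.
    groups, groups_y : GroupStructure or list of index arrays, optional
        Feature-to-network partition for X (and for Y; defaults to
        ``groups`` when p == q).  Required whenever alpha/beta > 0.
    variant : {"printed", "mm"}
        Reweighting convention for the group diagonal: ``"printed"`` uses
        1/(2|U_k| + eps); ``"mm"`` uses the majorization-consistent
        1/(|U_k| + eps), which guarantees a monotone objective trace.
    constraint : {"projected", "lagrangian", "constrained"}
        How the unit-variance constraints are handled.  "projected" (the
        conventional form) rescales each closed-form block solution onto
        its constraint; "lagrangian" leaves blocks unscaled so the
        quadratic terms act as soft constraints; "constrained" performs the
        exact penalized block minimization on the constraint set (a
        trust-region-style secular solve), which makes the objective trace
        provably non-increasing at the cost of an eigendecomposition per
        block update.
    epsilon : float
        Smoothing constant guarding zero denominators in the reweighting.
    tol, max_iter : stopping rule: max-abs change of (u, v, w) <= tol.
    init : {"ones", "random"}
    scale : bool
        Column-standardize X and Y and center/scale Z before fitting.
    random_state : int or None, for ``init="random"``.

    Attributes
    ----------
    u_, v_, w_ : fitted canonical weights (on the standardized scale).
    objective_trace_ : objective value at init and after every iteration.
    n_iter_, converged_ : loop metadata.
    """

    _mixes = True  # uses alpha/beta pathways

    def __init__(
        self,
        lambda1=1.0,
        lambda2=1.0,
        lambda3=1.0,
        alpha=0.5,
        beta=0.5,
        groups=None,
        groups_y=None,
        variant="printed",
        constraint="projected",
        epsilon=1e-6,
        tol=1e-5,
        max_iter=100,
        init="ones",
        scale=True,
        random_state=None,
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.alpha = alpha
        self.beta = beta
        self.groups = groups
        self.groups_y = groups_y
        self.variant = variant
        self.constraint = constraint
        self.epsilon = epsilon
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.scale = scale
        self.random_state = random_state

    # -- internal ----------------------------------------------------------
    def _hyper(self) -> HyperParams:
        return HyperParams(
            self.lambda1, self.lambda2, self.lambda3,
            self.alpha, self.beta, self.epsilon, self.tol, self.max_iter,
        )

    def _init_vec(self, d, M, rng):
        if self.init == "random":
            a = rng.standard_normal(d)
        elif self.init == "ones":
            a = np.ones(d)
        else:
            raise ValidationError(f"unknown init {self.init!r}")
        return scale_to_unit(M, a)

    def fit(self, X, Y, Z):
        """Fit on the three views; Z may be a DiagnosisVector, (n,) vector or
        (n, r) matrix."""
        hp = self._hyper()
        if self.variant not in ("printed", "mm"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.constraint not in ("projected", "lagrangian", "constrained"):
            raise ValidationError(f"unknown constraint {self.constraint!r}")
        X, Y, Z = _as_array(X), _as_array(Y), _as_array(Z)
        n, p = X.shape
        q, r = Y.shape[1], Z.shape[1]
        if Y.shape[0] != n or Z.shape[0] != n:
            raise ValidationError("views must share the subject axis")
        if self.scale:
            Xs, self.x_mean_, self.x_std_ = _standardize(X)
            Ys, self.y_mean_, self.y_std_ = _standardize(Y)
            Zs, self.z_mean_, self.z_std_ = _standardize(Z)
        else:
            Xs, Ys, Zs = X.astype(float), Y.astype(float), Z.astype(float)
            self.x_mean_ = np.zeros(p); self.x_std_ = np.ones(p)
            self.y_mean_ = np.zeros(q); self.y_std_ = np.ones(q)
            self.z_mean_ = np.zeros(r); self.z_std_ = np.ones(r)

        bx = _blocks(self.groups, p, "X") if self.alpha > 0 else (
            _blocks(self.groups, p, "X") if self.groups is not None else None
        )
        if self.alpha > 0 and bx is None:
            raise ValidationError("alpha > 0 requires a group structure for X")
        if self.groups_y is not None:
            by = _blocks(self.groups_y, q, "Y")
        elif bx is not None and q == p:
            by = bx
        else:
            by = None
        if self.beta > 0 and by is None:
            raise ValidationError("beta > 0 requires a group structure for Y")

        XtX, YtY, ZtZ = Xs.T @ Xs, Ys.T @ Ys, Zs.T @ Zs
        XtY, XtZ, YtZ = Xs.T @ Ys, Xs.T @ Zs, Ys.T @ Zs

        rng = np.random.default_rng(self.random_state)
        u = self._init_vec(p, Xs, rng)
        v = self._init_vec(q, Ys, rng)
        w = self._init_vec(r, Zs, rng)

        eps = self.epsilon
        variant = self.variant

        def gram_obj(u, v, w):
            # objective from the cached gram/cross matrices
            val = (
                -float(u @ (XtY @ v)) - float(v @ (YtZ @ w)) - float(w @ (XtZ.T @ u))
                + 0.5 * float(u @ (XtX @ u)) + 0.5 * float(v @ (YtY @ v))
                + 0.5 * float(w @ (ZtZ @ w))
            )
            if hp.alpha > 0 and bx is not None:
                val += hp.lambda1 * hp.alpha * group_norm(u, bx)
            val += hp.lambda1 * (1.0 - hp.alpha) * float(np.abs(u).sum())
            if hp.beta > 0 and by is not None:
                val += hp.lambda2 * hp.beta * group_norm(v, by)
            val += hp.lambda2 * (1.0 - hp.beta) * float(np.abs(v).sum())
            val += hp.lambda3 * float(np.abs(w).sum())
            return val

        def unit(G, a, what):
            nrm = np.sqrt(max(float(a @ (G @ a)), 0.0))
            if nrm == 0.0 or not np.isfinite(nrm):
                raise DegenerateWeightError(f"degenerate scaling of {what}")
            return a / nrm

        def block_step(G, rhs, a, lam, mix, blocks, what):
            dbar = _group_denoms(a, blocks, eps, variant) if (
                mix > 0 and blocks is not None
            ) else None
            d = 1.0 / (np.abs(a) + eps)
            if self.constraint == "constrained":
                P = lam * (1.0 - mix) * d
                if dbar is not None:
                    P = P + lam * mix * dbar
                return _constrained_block_solve(G, G + np.diag(P), rhs)
            new = _penalized_solve(G, rhs, lam, mix, d, dbar)
            if self.constraint == "projected":
                new = unit(G, new, what)
            return new

        trace = [gram_obj(u, v, w)]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            u0, v0, w0 = u, v, w
            u = block_step(
                XtX, XtY @ v + XtZ @ w, u, hp.lambda1, hp.alpha, bx, "u"
            )
            v = block_step(
                YtY, XtY.T @ u + YtZ @ w, v, hp.lambda2, hp.beta, by, "v"
            )
            w = block_step(
                ZtZ, XtZ.T @ u + YtZ.T @ v, w, hp.lambda3, 0.0, None, "w"
            )
            trace.append(gram_obj(u, v, w))
            delta = max(
                np.max(np.abs(u - u0)), np.max(np.abs(v - v0)), np.max(np.abs(w - w0))
            )
            if delta <= self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"alternating loop did not converge in {self.max_iter} iterations"
            )
        u, v, w = _canonical_sign(u, v, w)
        self.u_, self.v_, self.w_ = u, v, w
        self.objective_trace_ = trace
        self.n_iter_ = it
        self.converged_ = converged
        self.groups_x_blocks_ = bx
        self.groups_y_blocks_ = by
        return self

    def transform(self, X, Y):
        """Project new data onto the fitted canonical directions, applying
        the training standardization."""
        X, Y = _as_array(X), _as_array(Y)
        Xs = (X - self.x_mean_) / self.x_std_
        Ys = (Y - self.y_mean_) / self.y_std_
        return Xs @ self.u_, Ys @ self.v_

    def score(self, X, Y):
        """Canonical correlation coefficient of (Xu, Yv) on the given data."""
        s, t = self.transform(X, Y)
        if np.std(s) == 0.0 or np.std(t) == 0.0:
            raise NumericalError("zero-variance projection")
        return float(np.corrcoef(s, t)[0, 1])

    def weights_(self) -> TriViewWeights:
        return TriViewWeights(
            self.u_, self.v_, self.w_, list(self.objective_trace_),
            self.n_iter_, self.converged_,
        )


class MSCCA(BNMSCCA):
    """Three-view sparse CCA without the network penalty (alpha = beta = 0
    pathway of the same alternating machinery)."""

    def __init__(
        self,
        lambda1=1.0,
        lambda2=1.0,
        lambda3=1.0,
        epsilon=1e-6,
        tol=1e-5,
        max_iter=100,
        init="ones",
        scale=True,
        random_state=None,
    ):
        super().__init__(
            lambda1=lambda1,
            lambda2=lambda2,
            lambda3=lambda3,
            alpha=0.0,
            beta=0.0,
            groups=None,
            groups_y=None,
            variant="printed",
            constraint="projected",
            epsilon=epsilon,
            tol=tol,
            max_iter=max_iter,
            init=init,
            scale=scale,
            random_state=random_state,
        )


class SCCA(BaseEstimator):
    """Two-view sparse CCA in the penalized-matrix-decomposition style.

    Alternates u ~ S(X'Yv, d1) / |.|_2 and v ~ S(Y'Xu, d2) / |.|_2 where S
    is the soft-threshold operator and the threshold for each side is the
    fraction c1 (resp. c2) of the largest absolute entry of the update
    direction, so c in (0, 1] moves from dense to maximally sparse.  Only
    the first canonical pair is computed.
    """

    def __init__(self, c1=0.3, c2=0.3, tol=1e-6, max_iter=200, scale=True):
        self.c1 = c1
        self.c2 = c2
        self.tol = tol
        self.max_iter = max_iter
        self.scale = scale

    def _threshold_dir(self, a, c):
        delta = c * np.max(np.abs(a))
        out = soft_threshold(a, delta)
        if not np.any(out):
            warnings.warn(
                "sparsity budget infeasible: threshold removed every feature; "
                "keeping the least-sparse feasible solution"
            )
            j = int(np.argmax(np.abs(a)))
            out = np.zeros_like(a)
            out[j] = a[j]
        return out / np.linalg.norm(out)

    def _cross_target(self, Xs, Ys, Zs):
        # plain SCCA ignores Z; SCCAR overrides
        return Xs.T @ Ys, None, None

    def fit(self, X, Y, Z=None):
        for c in (self.c1, self.c2):
            if not (0.0 < c <= 1.0):
                raise ValidationError("c1, c2 must lie in (0, 1]")
        X, Y = _as_array(X), _as_array(Y)
        if Y.shape[0] != X.shape[0]:
            raise ValidationError("views must share the subject axis")
        Zs = None
        if Z is not None:
            Z = _as_array(Z)
            Zs, self.z_mean_, self.z_std_ = _standardize(Z)
        if self.scale:
            Xs, self.x_mean_, self.x_std_ = _standardize(X)
            Ys, self.y_mean_, self.y_std_ = _standardize(Y)
        else:
            Xs, Ys = X.astype(float), Y.astype(float)
            self.x_mean_ = np.zeros(X.shape[1]); self.x_std_ = np.ones(X.shape[1])
            self.y_mean_ = np.zeros(Y.shape[1]); self.y_std_ = np.ones(Y.shape[1])
        C, tx, ty = self._cross_target(Xs, Ys, Zs)
        # deterministic init: leading right singular vector of the cross matrix
        _, _, Vt = np.linalg.svd(C, full_matrices=False)
        v = Vt[0]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        u = np.zeros(Xs.shape[1])
        it = 0
        converged = False
        for it in range(1, self.max_iter + 1):
            u0, v0 = u, v
            a = C @ v if tx is None else C @ v + tx
            u = self._threshold_dir(a, self.c1)
            b = C.T @ u if ty is None else C.T @ u + ty
            v = self._threshold_dir(b, self.c2)
            if max(np.max(np.abs(u - u0)), np.max(np.abs(v - v0))) <= self.tol:
                converged = True
                break
        if u[np.argmax(np.abs(u))] < 0:
            u, v = -u, -v
        self.u_, self.v_ = u, v
        self.n_iter_ = it
        self.converged_ = converged
        self.correlation_ = ccc(Xs, Ys, u, v)
        return self

    def transform(self, X, Y):
        X, Y = _as_array(X), _as_array(Y)
        Xs = (X - self.x_mean_) / self.x_std_
        Ys = (Y - self.y_mean_) / self.y_std_
        return Xs @ self.u_, Ys @ self.v_

    def score(self, X, Y):
        s, t = self.transform(X, Y)
        if np.std(s) == 0.0 or np.std(t) == 0.0:
            raise NumericalError("zero-variance projection")
        return float(np.corrcoef(s, t)[0, 1])


class SCCAR(SCCA):
    """SCCA with a diagnosis-regression pull: each view's update direction is
    augmented by gamma * (view)'Z so that features aligned with the diagnosis
    gain weight.  With gamma = 0 this reduces exactly to SCCA.  The original
    formulation is not printed in full anywhere public, so this baseline is a
    faithful-intent reconstruction of "linear regression combined with SCCA".
    """

    def __init__(self, c1=0.3, c2=0.3, gamma=1.0, tol=1e-6, max_iter=200, scale=True):
        super().__init__(c1=c1, c2=c2, tol=tol, max_iter=max_iter, scale=scale)
        self.gamma = gamma

    def _cross_target(self, Xs, Ys, Zs):
        C = Xs.T @ Ys
        if Zs is None or self.gamma == 0.0:
            return C, None, None
        z = Zs[:, 0]
        return C, self.gamma * (Xs.T @ z), self.gamma * (Ys.T @ z)

    def fit(self, X, Y, Z=None):
        if Z is None and self.gamma != 0.0:
            raise ValidationError("SCCAR with gamma != 0 requires the diagnosis Z")
        return super().fit(X, Y, Z)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_bn_mscca(X, Y, Z, groups, hp: HyperParams | None = None, *, groups_y=None,
                 variant="printed", constraint="projected", init="ones",
                 scale=True, seed=None) -> TriViewWeights:
    hp = hp or HyperParams()
    est = BNMSCCA(
        hp.lambda1, hp.lambda2, hp.lambda3, hp.alpha, hp.beta,
        groups=groups, groups_y=groups_y, variant=variant, constraint=constraint,
        epsilon=hp.epsilon, tol=hp.tol, max_iter=hp.max_iter, init=init,
        scale=scale, random_state=seed,
    ).fit(X, Y, Z)
    return est.weights_()


def fit_mscca(X, Y, Z, hp: HyperParams | None = None, *, init="ones",
              scale=True, seed=None) -> TriViewWeights:
    hp = hp or HyperParams()
    est = MSCCA(
        hp.lambda1, hp.lambda2, hp.lambda3, epsilon=hp.epsilon, tol=hp.tol,
        max_iter=hp.max_iter, init=init, scale=scale, random_state=seed,
    ).fit(X, Y, Z)
    return est.weights_()


def fit_scca(X, Y, c1=0.3, c2=0.3, **kwargs):
    est = SCCA(c1=c1, c2=c2, **kwargs).fit(X, Y)
    return est.u_, est.v_, est.correlation_


def fit_sccar(X, Y, Z, c1=0.3, c2=0.3, gamma=1.0, **kwargs):
    est = SCCAR(c1=c1, c2=c2, gamma=gamma, **kwargs).fit(X, Y, Z)
    return est.u_, est.v_, est.correlation_
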