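"""Covariate adjustment: residualize feature columns on age/gender by OLS.

Each feature column is replaced by the residual of its least-squares fit on
an intercept plus the covariates, removing linear age and gender effects
before any association analysis.  By default the regression is fitted on the
full sample; ``fit_on`` lets leakage-sensitive pipelines fit the projection
on a training subset only and apply it everywhere.
"""

from __future__ import annotations

import numpy as np

from .datamodel import CovariateTable, FeatureMatrix
from .exceptions import AlignmentError, ValidationError

__all__ = ["residualize", "residualize_array"]


def _design(C: np.ndarray, names, add_intercept: bool) -> tuple[np.ndarray, list[str]]:
    if add_intercept:
        C = np.column_stack([np.ones(C.shape[0]), C])
        names = ["intercept", *names]
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # name columns involved in the collinearity by leave-one-out rank
        bad = [
            names[j]
            for j in range(C.shape[1])
            if np.linalg.matrix_rank(np.delete(C, j, axis=1)) == rank
        ]
        raise ValidationError(f"rank-deficient covariate design; collinear: {bad}")
    return C, list(names)


def residualize_array(values, covariates, names=None, add_intercept=True,
                      fit_on=None) -> np.ndarray:
    """Residualize the columns of ``values`` on the covariate design.

    ``fit_on`` (optional boolean/index array over rows) restricts the OLS fit
    to a subset; the fitted coefficients are then applied to every row.
    """
    V = np.asarray(values, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != V.shape[0]:
        C = C.T
    if C.shape[0] != V.shape[0]:
        raise AlignmentError("covariates do not align with the feature rows")
    if names is None:
        names = [f"cov{j}" for j in range(C.shape[1])]
    D, _ = _design(C, names, add_intercept)
    if fit_on is None:
        beta, *_ = np.linalg.lstsq(D, V, rcond=None)
    else:
        idx = np.asarray(fit_on)
        beta, *_ = np.linalg.lstsq(D[idx], V[idx], rcond=None)
    return V - D @ beta


def residualize(features: FeatureMatrix, covariates: CovariateTable,
                add_intercept: bool = True, fit_on=None) -> FeatureMatrix:
    """Return a FeatureMatrix whose columns are OLS residuals on the covariates."""
    if features.subject_ids != covariates.subject_ids:
        raise AlignmentError("feature and covariate subject ids differ")
    resid = residualize_array(
        features.values, covariates.design, covariates.columns,
        add_intercept=add_intercept, fit_on=fit_on,
    )
    return FeatureMatrix(
        resid, features.subject_ids, features.feature_labels, features.modality
    )
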