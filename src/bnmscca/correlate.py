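"""Pearson correlation utilities for biomarker follow-up analyses.

Pairwise correlations between selected features of the two modalities, and
per-feature correlations with (possibly incomplete) clinical symptom
scores.  p-values use the exact t-transform of r; raw p < 0.05 is the
conventional significance level here, with an optional Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError

__all__ = ["pairwise_corr", "significance_mask", "symptom_corr"]


def _r_to_p(r, n):
    """Two-sided p for Pearson r via the exact t distribution (n-2 df)."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def pairwise_corr(A, B) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p for every column pair of A (n x a) and
    B (n x b); constant columns give NaN entries with a warning."""
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValidationError("A and B must share the subject axis")
    n = A.shape[0]
    if n < 3:
        raise InsufficientDataError("need at least 3 subjects")
    sa = A.std(axis=0)
    sb = B.std(axis=0)
    const = (sa == 0, sb == 0)
    if const[0].any() or const[1].any():
        warnings.warn("constant column(s): correlation undefined (NaN)")
    Ac = (A - A.mean(axis=0)) / np.where(sa > 0, sa, np.nan)
    Bc = (B - B.mean(axis=0)) / np.where(sb > 0, sb, np.nan)
    r = (Ac.T @ Bc) / n
    p = _r_to_p(r, n)
    return r, p


def significance_mask(p, alpha=0.05, adjust=None) -> np.ndarray:
    """Boolean mask of significant entries; ``adjust="bh"`` applies the
    Benjamini-Hochberg step-up over all finite p-values."""
    p = np.asarray(p, float)
    if adjust is None:
        return p < alpha
    if adjust != "bh":
        raise ValidationError(f"unknown adjustment {adjust!r}")
    out = np.zeros(p.shape, bool)
    finite = np.isfinite(p)
    q = stats.false_discovery_control(p[finite], method="bh")
    out[finite] = q < alpha
    return out


def symptom_corr(features, scores, labels=None, method="pearson") -> pd.DataFrame:
    """Per-feature correlation with a symptom score over complete cases.

    ``scores`` may contain NaN for subjects without the score; those rows
    are dropped feature-wise (complete-case analysis).  Returns a DataFrame
    with columns feature, r, p, n_used.
    """
    X = np.atleast_2d(np.asarray(features, float))
    if X.shape[0] == 1 and np.asarray(scores).size != 1:
        X = X.T
    s = np.asarray(scores, float).ravel()
    if X.shape[0] != s.size:
        raise ValidationError("features and scores must share the subject axis")
    mask = np.isfinite(s)
    n_used = int(mask.sum())
    if n_used < 3:
        raise InsufficientDataError(
            f"only {n_used} subjects with a score; need at least 3"
        )
    if labels is None:
        labels = [f"f{j}" for j in range(X.shape[1])]
    rows = []
    for j, lab in enumerate(labels):
        x = X[mask, j]
        y = s[mask]
        if method == "pearson":
            res = stats.pearsonr(x, y)
        elif method == "spearman":
            res = stats.spearmanr(x, y)
        else:
            raise ValidationError(f"unknown method {method!r}")
        rows.append({"feature": str(lab), "r": float(res.statistic),
                     "p": float(res.pvalue), "n_used": n_used})
    return pd.DataFrame(rows)
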