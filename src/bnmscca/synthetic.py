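"""Synthetic multi-view fixtures with known ground truth.

The generators emulate the statistical structure the three-view model
assumes: a shared latent factor loads on whole networks of features in two
imaging-like views, and a thresholded version of the same factor provides a
balanced binary diagnosis.  Ground-truth weight supports are returned so
recovery can be scored.  BOLD-like panels and demographic/symptom tables are
provided for the d-fALFF and correlation stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CovariateTable, GroupStructure
from .dynfalff import TimeSeriesPanel
from .exceptions import ValidationError

__all__ = [
    "MultiViewSample",
    "generate_multiview",
    "generate_groups",
    "generate_bold_panel",
    "generate_demographics",
    "planted_score",
]


def generate_groups(p: int, K: int, feature_labels=None) -> GroupStructure:
    """Split p features into K contiguous, near-equal networks."""
    if K < 1 or K > p:
        raise ValidationError("need 1 <= K <= p")
    sizes = np.full(K, p // K)
    sizes[: p % K] += 1
    nets = np.repeat([f"net{k}" for k in range(K)], sizes)
    return GroupStructure.from_labels(nets, feature_labels)


@dataclass
class MultiViewSample:
    """Generated views plus the ground truth that produced them."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray          # (n,) binary diagnosis 0/1
    true_u: np.ndarray
    true_v: np.ndarray
    latent: np.ndarray
    groups: GroupStructure
    active_networks: list[str]


def _planted_weights(rng, d, blocks, active_idx):
    w = np.zeros(d)
    for k in active_idx:
        b = blocks[k]
        # keep "active" features clearly away from zero so support recovery
        # is well posed
        w[b] = np.abs(rng.standard_normal(b.size)) + 0.5
    return w


def generate_multiview(
    n: int,
    p: int,
    q: int,
    groups: GroupStructure | None = None,
    active_networks=None,
    latent_corr: float = 0.6,
    diag_effect: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | None = 0,
    K: int = 15,
    n_active: int = 2,
) -> MultiViewSample:
    """Two feature views sharing a network-sparse latent signal plus a
    correlated binary diagnosis.

    A latent factor s ~ N(0, 1) of length n is drawn; true_u (true_v) is
    nonzero exactly on the features of the active networks; the views are
    X = latent_corr * s true_u' + noise_sd * E and likewise for Y.  The
    diagnosis is the latent factor scaled by ``diag_effect`` plus unit
    noise, thresholded at its median so the two classes stay balanced.
    """
    if not (0.0 <= latent_corr <= 1.0):
        raise ValidationError("latent_corr must lie in [0, 1]")
    if groups is None:
        groups = generate_groups(p, K)
    if q != p and len(groups.feature_labels) != p:
        raise ValidationError("groups must describe the p features of X")
    rng = np.random.default_rng(seed)
    nets = groups.network_labels
    if active_networks is None:
        active_networks = list(nets[:n_active])
    active_networks = [str(a) for a in active_networks]
    unknown = [a for a in active_networks if a not in nets]
    if unknown:
        raise ValidationError(f"unknown networks: {unknown}")
    if latent_corr > 0 and not active_networks:
        raise ValidationError("latent_corr > 0 needs at least one active network")
    active_idx = [nets.index(a) for a in active_networks]

    s = rng.standard_normal(n)
    true_u = _planted_weights(rng, p, groups.index_blocks, active_idx)
    if q == p:
        true_v = _planted_weights(rng, q, groups.index_blocks, active_idx)
    else:
        gy = generate_groups(q, groups.K)
        true_v = _planted_weights(rng, q, gy.index_blocks, active_idx)
    X = latent_corr * np.outer(s, true_u) + noise_sd * rng.standard_normal((n, p))
    Y = latent_corr * np.outer(s, true_v) + noise_sd * rng.standard_normal((n, q))
    z_latent = diag_effect * s + rng.standard_normal(n)
    Z = (z_latent > np.median(z_latent)).astype(float)
    return MultiViewSample(X, Y, Z, true_u, true_v, s, groups, active_networks)


def generate_bold_panel(
    n_units: int,
    T: int,
    tr: float = 2.0,
    band_power=((0.01, 0.1, 1.0),),
    broadband: float = 0.2,
    nonstationary: float = 0.0,
    seed: int | None = 0,
) -> TimeSeriesPanel:
    """BOLD-like series built in the frequency domain.

    ``band_power`` is a list of (low Hz, high Hz, amplitude) triples: rfft
    coefficients inside each band get the stated amplitude with random
    phases; ``broadband`` adds white noise everywhere.  ``nonstationary``
    multiplies each series by a slow random envelope of that relative
    amplitude, creating across-window variability for d-fALFF.
    """
    if T < 4:
        raise ValidationError("T too short")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(T, d=tr)
    series = np.empty((n_units, T))
    for i in range(n_units):
        coef = np.zeros(freqs.size, dtype=complex)
        for low, high, amp in band_power:
            sel = (freqs >= low) & (freqs <= high)
            phases = rng.uniform(0, 2 * np.pi, sel.sum())
            coef[sel] += amp * np.exp(1j * phases)
        x = np.fft.irfft(coef, n=T) * T
        x = x + broadband * rng.standard_normal(T)
        if nonstationary > 0:
            t = np.arange(T)
            envelope = 1.0 + nonstationary * np.sin(
                2 * np.pi * rng.uniform(0.5, 1.5) * t / T + rng.uniform(0, 2 * np.pi)
            )
            x = x * envelope
        series[i] = x
    return TimeSeriesPanel(series, tr)


def generate_demographics(
    n: int,
    seed: int | None = 0,
    missing_fraction: float = 0.435,
    age_mean: float = 23.2,
    age_sd: float = 6.5,
):
    """Covariates (age, gender) and PANSS-like symptom scores.

    Ages follow a truncated normal around the young-adult cohort mean;
    gender is balanced 0/1.  Symptom subscores (positive, negative,
    general) are present for a ``1 - missing_fraction`` share of subjects
    (defaults mirror 108 complete records out of 191) and NaN elsewhere.
    """
    import pandas as pd

    if n < 2:
        raise ValidationError("need n >= 2")
    rng = np.random.default_rng(seed)
    ages = np.clip(rng.normal(age_mean, age_sd, n), 16, 60)
    gender = np.zeros(n)
    gender[rng.permutation(n)[: n // 2]] = 1.0
    ids = [f"s{i:04d}" for i in range(n)]
    cov = CovariateTable(
        pd.DataFrame({"age": ages, "gender": gender}), ids
    )
    scores = pd.DataFrame(
        {
            "positive": np.clip(rng.normal(20, 5, n), 7, 49),
            "negative": np.clip(rng.normal(20, 6, n), 7, 49),
            "general": np.clip(rng.normal(38, 9, n), 16, 112),
        },
        index=ids,
    )
    n_missing = int(round(missing_fraction * n))
    if n_missing:
        miss = rng.permutation(n)[:n_missing]
        scores.iloc[miss] = np.nan
    return cov, scores


def planted_score(feature, rho: float, seed: int | None = 0) -> np.ndarray:
    """A score vector with population correlation ``rho`` to ``feature``."""
    if not (-1.0 <= rho <= 1.0):
        raise ValidationError("rho must lie in [-1, 1]")
    x = np.asarray(feature, dtype=float).ravel()
    sd = x.std()
    if sd == 0:
        raise ValidationError("feature is constant")
    z = (x - x.mean()) / sd
    rng = np.random.default_rng(seed)
    return rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(x.size)
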