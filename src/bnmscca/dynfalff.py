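"""Sliding-window fALFF and its temporal coefficient of variation (d-fALFF).

fALFF of a windowed BOLD series is the ratio of summed one-sided FFT
amplitude (square root of power) inside a low-frequency band — 0.01-0.1 Hz
by convention — to the summed amplitude over the whole non-DC range up to
Nyquist.  d-fALFF is the coefficient of variation (std / mean) of the
per-window fALFF values, a measure of how variable the low-frequency
fluctuation amplitude is over time.  Voxel/unit maps are normalized by the
whole-brain mean and averaged within atlas regions to give ROI features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InfeasibleWindowError, NumericalError, ValidationError

__all__ = [
    "TimeSeriesPanel",
    "WindowSpec",
    "DynFalffResult",
    "sliding_windows",
    "falff",
    "dfalff",
    "dfalff_full",
    "normalize_global",
    "roi_reduce",
]


@dataclass
class TimeSeriesPanel:
    """Units (voxels or ROIs) x timepoints BOLD series with its TR."""

    series: np.ndarray
    sampling_interval: float  # TR, seconds
    unit_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be positive")
        if self.unit_labels is None:
            self.unit_labels = [f"unit{i}" for i in range(self.series.shape[0])]
        if len(self.unit_labels) != self.series.shape[0]:
            raise ValidationError("unit_labels length mismatch")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass
class WindowSpec:
    """Sliding-window geometry (seconds) and spectral band (Hz).

    Defaults follow common dynamic-fALFF practice: 60 s windows moved in
    10 s steps, band 0.01-0.1 Hz.
    """

    width_s: float = 60.0
    step_s: float = 10.0
    band: tuple[float, float] = (0.01, 0.1)

    def __post_init__(self) -> None:
        if self.width_s <= 0 or self.step_s <= 0:
            raise ValidationError("window width and step must be positive")
        low, high = self.band
        if not (0.0 <= low < high):
            raise ValidationError(f"invalid band {self.band}")


def sliding_windows(T: int, tr: float, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open 0-based (start, end) index ranges of the sliding windows.

    Window length L = round(width_s / tr) samples, step S = round(step_s / tr);
    ranges are [i*S, i*S + L) for i = 0 .. floor((T - L) / S), i.e.
    floor((T - L)/S) + 1 windows in total.
    """
    if tr <= 0:
        raise ValidationError("tr must be positive")
    L = int(round(spec.width_s / tr))
    S = int(round(spec.step_s / tr))
    if L < 2:
        raise ValidationError(f"window of {L} samples is too short")
    if S < 1:
        raise ValidationError("step must span at least one sample")
    if L > T:
        raise InfeasibleWindowError(
            f"window of {L} samples does not fit into {T} timepoints"
        )
    n_win = (T - L) // S + 1
    return [(i * S, i * S + L) for i in range(n_win)]


def falff(series, tr: float, band=(0.01, 0.1), on_constant: str = "raise") -> float:
    """Fractional amplitude of low-frequency fluctuation of one series.

    The one-sided amplitude spectrum (|rfft|, no taper) is summed over bins
    with band[0] <= f <= band[1] and divided by the sum over all non-DC bins
    up to and including Nyquist.  The DC bin is excluded from the denominator
    because it reflects the signal mean, not fluctuation.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("series must have at least 2 samples")
    if tr <= 0:
        raise ValidationError("tr must be positive")
    nyquist = 0.5 / tr
    low, high = band
    if not (0.0 <= low < high <= nyquist + 1e-12):
        raise ValidationError(f"band {band} outside (0, Nyquist={nyquist}]")
    amp = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=tr)
    denom = amp[1:].sum()
    if denom == 0.0:
        if on_constant == "nan":
            return float("nan")
        raise NumericalError("constant series: fALFF ratio undefined")
    in_band = (freqs >= low) & (freqs <= high)
    in_band[0] = False
    return float(amp[in_band].sum() / denom)


@dataclass
class DynFalffResult:
    """d-fALFF values plus the per-window fALFF maps they were derived from."""

    values: np.ndarray           # CV per unit
    per_window: np.ndarray       # units x windows fALFF
    mean_map: np.ndarray
    std_map: np.ndarray
    windows: list[tuple[int, int]]


def dfalff_full(panel: TimeSeriesPanel, spec: WindowSpec | None = None,
                ddof: int = 1) -> DynFalffResult:
    """Per-unit coefficient of variation of window-fALFF, with intermediates.

    Units whose mean window-fALFF is zero (or whose windows are all constant)
    yield NaN and a warning.  ``ddof=1`` uses the sample standard deviation.
    """
    spec = spec or WindowSpec()
    wins = sliding_windows(panel.n_timepoints, panel.sampling_interval, spec)
    if len(wins) < 2:
        raise InfeasibleWindowError(
            f"need at least 2 windows for a CV, got {len(wins)}"
        )
    per_window = np.empty((panel.series.shape[0], len(wins)))
    for j, (a, b) in enumerate(wins):
        seg = panel.series[:, a:b]
        for i in range(seg.shape[0]):
            per_window[i, j] = falff(
                seg[i], panel.sampling_interval, spec.band, on_constant="nan"
            )
    mean_map = per_window.mean(axis=1)
    std_map = per_window.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = std_map / mean_map
    bad = ~np.isfinite(per_window).all(axis=1) | (mean_map == 0.0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} unit(s) have undefined d-fALFF (NaN)")
        cv[bad] = np.nan
    return DynFalffResult(cv, per_window, mean_map, std_map, wins)


def dfalff(panel: TimeSeriesPanel, spec: WindowSpec | None = None,
           ddof: int = 1) -> np.ndarray:
    """One d-fALFF value (CV of window-fALFF) per unit."""
    return dfalff_full(panel, spec, ddof).values


def normalize_global(dfalff_map, mask=None) -> np.ndarray:
    """Divide by the mean over the (brain) mask so the masked mean becomes 1."""
    x = np.asarray(dfalff_map, dtype=float)
    m = np.ones(x.shape, bool) if mask is None else np.asarray(mask, bool)
    if m.shape != x.shape:
        raise ValidationError("mask shape mismatch")
    if not m.any():
        raise ValidationError("mask selects no units")
    mean = x[m].mean()
    if mean == 0.0:
        raise NumericalError("masked mean is zero: cannot normalize")
    return x / mean


def roi_reduce(unit_map, atlas_labels, roi_ids) -> np.ndarray:
    """Average a unit-level map within each atlas region, ordered by roi_ids."""
    x = np.asarray(unit_map, dtype=float).ravel()
    labels = np.asarray(atlas_labels).ravel()
    if labels.size != x.size:
        raise ValidationError("atlas labels must align with the unit map")
    out = np.empty(len(roi_ids))
    for i, roi in enumerate(roi_ids):
        sel = labels == roi
        if not sel.any():
            raise ValidationError(f"ROI {roi!r} has no member units")
        out[i] = x[sel].mean()
    return out
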