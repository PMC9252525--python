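import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnmscca.dynfalff import (
    TimeSeriesPanel,
    WindowSpec,
    dfalff,
    dfalff_full,
    falff,
    normalize_global,
    roi_reduce,
    sliding_windows,
)
from bnmscca.exceptions import InfeasibleWindowError, NumericalError, ValidationError

SPEC = WindowSpec(width_s=60.0, step_s=10.0, band=(0.01, 0.1))


class TestSlidingWindows:
    def test_standard_acquisition_geometry(self):
        # 188 volumes minus 10 dummies at TR=2 s; 60 s windows, 10 s steps
        wins = sliding_windows(178, 2.0, SPEC)
        assert len(wins) == 30
        assert wins[0] == (0, 30)
        assert wins[-1] == (145, 175)

    def test_single_window_boundary(self):
        assert sliding_windows(30, 2.0, SPEC) == [(0, 30)]

    def test_infeasible_window(self):
        with pytest.raises(InfeasibleWindowError):
            sliding_windows(29, 2.0, SPEC)

    @given(T=st.integers(2, 500), L=st.integers(2, 500), S=st.integers(1, 50))
    @settings(max_examples=200, deadline=None)
    def test_count_formula(self, T, L, S):
        spec = WindowSpec(width_s=L * 2.0, step_s=S * 2.0)
        if L > T:
            with pytest.raises(InfeasibleWindowError):
                sliding_windows(T, 2.0, spec)
        else:
            wins = sliding_windows(T, 2.0, spec)
            assert len(wins) == (T - L) // S + 1
            assert all(b - a == L for a, b in wins)
            assert wins[-1][1] <= T


class TestFalff:
    def test_in_band_sine_is_one(self):
        # 0.05 Hz is bin-aligned for L=120, TR=2 (bin width 1/240 Hz)
        t = np.arange(120) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        assert falff(x, 2.0) == pytest.approx(1.0, abs=1e-6)

    def test_out_of_band_sine_is_zero(self):
        t = np.arange(120) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        assert falff(x, 2.0) == pytest.approx(0.0, abs=1e-6)

    def test_white_noise_matches_flat_spectrum_fraction(self):
        # E[falff] for white noise ~ fraction of non-DC bins inside the band
        rng = np.random.default_rng(7)
        L, tr = 300, 2.0
        freqs = np.fft.rfftfreq(L, tr)
        frac = ((freqs >= 0.01) & (freqs <= 0.1)).sum() / (freqs.size - 1)
        vals = [falff(rng.standard_normal(L), tr) for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(frac, abs=0.01)

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.standard_normal(100)
        assert falff(3.7 * x, 2.0) == pytest.approx(falff(x, 2.0), rel=1e-12)

    def test_constant_series_policy(self):
        with pytest.raises(NumericalError):
            falff(np.ones(50), 2.0)
        assert np.isnan(falff(np.ones(50), 2.0, on_constant="nan"))


class TestDfalff:
    def test_hand_computed_cv(self):
        # CV of window-fALFFs 0.2 and 0.4: sample std 0.1414.. / mean 0.3
        vals = np.array([0.2, 0.4])
        expect = vals.std(ddof=1) / vals.mean()
        assert expect == pytest.approx(0.4714, abs=1e-4)
        # stationary in-band signal: identical windows give CV ~ 0
        t = np.arange(120) * 2.0
        panel = TimeSeriesPanel(np.sin(2 * np.pi * 0.05 * t)[None, :], 2.0)
        out = dfalff(panel, WindowSpec(width_s=60, step_s=60))
        assert out[0] == pytest.approx(0.0, abs=1e-6)

    def test_constant_unit_flagged_nan(self):
        rng = np.random.default_rng(0)
        series = np.vstack([rng.standard_normal(178), np.ones(178)])
        panel = TimeSeriesPanel(series, 2.0)
        with pytest.warns(UserWarning, match="undefined"):
            out = dfalff(panel, SPEC)
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_insufficient_windows(self):
        panel = TimeSeriesPanel(np.random.default_rng(0).standard_normal((1, 30)), 2.0)
        with pytest.raises(InfeasibleWindowError):
            dfalff(panel, SPEC)

    def test_full_result_keeps_per_window_maps(self):
        rng = np.random.default_rng(1)
        panel = TimeSeriesPanel(rng.standard_normal((3, 178)), 2.0)
        res = dfalff_full(panel, SPEC)
        assert res.per_window.shape == (3, 30)
        np.testing.assert_allclose(res.mean_map, res.per_window.mean(axis=1))
        np.testing.assert_allclose(
            res.values, res.std_map / res.mean_map, atol=1e-12
        )

    def test_raw_amplitude_scaling_invariance(self, rng):
        x = rng.standard_normal((2, 178))
        p1 = TimeSeriesPanel(x, 2.0)
        p2 = TimeSeriesPanel(5.0 * x, 2.0)
        np.testing.assert_allclose(dfalff(p1, SPEC), dfalff(p2, SPEC), rtol=1e-10)


class TestNormalizeAndReduce:
    def test_forced_values(self):
        np.testing.assert_allclose(normalize_global([2, 4, 6]), [0.5, 1.0, 1.5])
        np.testing.assert_allclose(normalize_global([3.3, 3.3]), [1.0, 1.0])

    def test_masked_mean_is_one(self, rng):
        x = rng.standard_normal(50) + 5
        mask = rng.random(50) > 0.3
        out = normalize_global(x, mask)
        assert out[mask].mean() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out, x / x[mask].mean(), atol=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(NumericalError):
            normalize_global([1.0, -1.0])

    def test_roi_reduce_hand_case_and_oracle(self, rng):
        np.testing.assert_allclose(
            roi_reduce([1, 3, 5, 7], [1, 1, 2, 2], [1, 2]), [2.0, 6.0]
        )
        x = rng.standard_normal(200)
        labels = rng.integers(1, 6, 200)
        got = roi_reduce(x, labels, [1, 2, 3, 4, 5])
        want = [x[labels == r].mean() for r in range(1, 6)]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValidationError, match="no member"):
            roi_reduce([1.0, 2.0], [1, 1], [1, 2])
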