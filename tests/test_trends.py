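"""Tests for robust slopes, FDR, changepoints, endpoints, PSD utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscitrack import (
    SlopeEstimate, bh_fdr, block_average, endpoints_from_fit,
    percent_positive, robust_slope, slope_change_likelihood, slope_map,
    welch_psd,
)
from oscitrack.trends import best_breakpoint

FS = 4.0   # trend fits run at a few Hz; white-noise calibration uses this


class TestRobustSlope:
    def test_noiseless_line_exact(self):
        t_h = np.arange(int(3600 * FS)) / FS / 3600.0
        est = robust_slope(2.0 * t_h + 5.0, FS)
        assert est.slope == pytest.approx(2.0, rel=1e-9)
        assert est.intercept == pytest.approx(5.0, rel=1e-9)
        assert est.p_value < 1e-10

    def test_outlier_resistance_vs_ols(self):
        """5% gross outliers: the bisquare fit stays within 5% of the true
        slope while ordinary least squares (the oracle contrast) does not."""
        rng = np.random.default_rng(2)
        n = int(1200 * FS)
        t_h = np.arange(n) / FS / 3600.0
        y = 3.0 * t_h + 0.05 * rng.standard_normal(n)
        out_idx = rng.choice(n, size=n // 20, replace=False)
        y[out_idx] += 40.0 * np.sign(t_h[out_idx] - t_h.mean())  # leveraged
        est = robust_slope(y, FS)
        ols = np.polyfit(t_h, y, 1)[0]
        assert est.slope == pytest.approx(3.0, rel=0.05)
        assert abs(ols - 3.0) > abs(est.slope - 3.0)

    def test_false_positive_rate_calibrated(self):
        """White-noise trajectories: ~5% of fits significant at alpha=0.05
        (within the binomial 95% band for 100 runs)."""
        rng = np.random.default_rng(0)
        hits = sum(
            robust_slope(rng.standard_normal(int(150 * FS)), FS).p_value < 0.05
            for _ in range(100))
        assert 1 <= hits <= 10   # central 95% of Binomial(100, 0.05)

    def test_agrees_with_ols_on_clean_gaussian(self):
        """On clean Gaussian data the bisquare IRLS matches ordinary least
        squares closely (bisquare weights are smooth, so the match is
        near- rather than bit-exact), and exactly on a perfect line."""
        rng = np.random.default_rng(4)
        n = int(600 * FS)
        t_h = np.arange(n) / FS / 3600.0
        y = 1.5 * t_h + 0.01 * rng.standard_normal(n)
        est = robust_slope(y, FS)
        ols = np.polyfit(t_h, y, 1)[0]
        assert est.slope == pytest.approx(ols, rel=1e-3)
        # exact-line case: weights are all unity, estimates coincide
        exact = robust_slope(1.5 * t_h, FS)
        assert exact.slope == pytest.approx(1.5, rel=1e-9)

    def test_constant_trajectory_degenerate(self):
        est = robust_slope(np.full(int(60 * FS), 7.0), FS)
        assert est.slope == 0.0
        assert est.p_value == 1.0
        assert est.degenerate

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            robust_slope(np.zeros(8), FS)

    def test_decimation_preserves_slope(self):
        fs = 120.0
        t_h = np.arange(int(600 * fs)) / fs / 3600.0
        rng = np.random.default_rng(1)
        y = -2.0 * t_h + 0.1 * rng.standard_normal(t_h.size)
        full = robust_slope(y, fs, decimate_to=None)
        dec = robust_slope(y, fs, decimate_to=4.0)
        assert dec.slope == pytest.approx(full.slope, rel=0.02)


class TestBlockAverage:
    def test_length_and_rate(self):
        x = np.arange(1000, dtype=float)
        y, fs2 = block_average(x, 120.0, 4.0)
        assert fs2 == pytest.approx(4.0)
        assert y.size == 1000 // 30

    def test_noop_when_rate_matches(self):
        x = np.arange(100, dtype=float)
        y, fs2 = block_average(x, 4.0, 4.0)
        assert np.array_equal(x, y) and fs2 == 4.0


def brute_force_bh(p, q):
    """Literal step-up rule: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestBHFDR:
    def test_textbook_examples(self):
        flags, _ = bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05)
        assert flags.all()
        flags, _ = bh_fdr([0.9, 0.8], 0.05)
        assert not flags.any()
        flags, _ = bh_fdr([0.04], 0.05)
        assert flags.all()

    def test_empty_input(self):
        flags, adj = bh_fdr([], 0.05)
        assert flags.size == 0 and adj.size == 0

    def test_never_rejects_more_than_uncorrected(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(10)
            flags, _ = bh_fdr(p, 0.05)
            assert flags.sum() <= (p <= 0.05).sum()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_brute_force_step_up(self, p):
        flags, _ = bh_fdr(p, 0.05)
        assert np.array_equal(flags, brute_force_bh(p, 0.05))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5], 0.05)


class TestBreakpointAndLikelihood:
    def test_shared_break_detected(self):
        """All channels kink at T/2: the likelihood peaks there."""
        fs = 4.0
        n = int(1200 * fs)
        t = np.arange(n) / fs
        rng = np.random.default_rng(0)
        trajs = np.vstack([
            np.where(t < t[n // 2], 0.002 * t, 0.002 * t[n // 2]
                     - 0.002 * (t - t[n // 2])) + 0.01 * rng.standard_normal(n)
            for _ in range(6)])
        cl = slope_change_likelihood(trajs, fs, kernel_sigma_min=1.0,
                                     decimate_to=None)
        t_mid = t[n // 2] / 60.0
        assert abs(cl.t_min[np.argmax(cl.likelihood)] - t_mid) < 2.0

    def test_likelihood_sums_to_one(self):
        rng = np.random.default_rng(1)
        trajs = rng.standard_normal((4, int(1200 * 4.0)))
        cl = slope_change_likelihood(trajs, 4.0, kernel_sigma_min=1.0,
                                     decimate_to=None)
        assert cl.likelihood.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(cl.likelihood >= 0)

    def test_no_break_gives_diffuse_likelihood(self):
        """Pure lines plus noise: detected breakpoints are scattered, so
        the peak stays below 3x the uniform density in most seeded runs."""
        fs = 4.0
        n = int(1800 * fs)
        t_h = np.arange(n) / fs / 3600.0
        ok = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            trajs = np.vstack([2.0 * t_h + 0.5 * rng.standard_normal(n)
                               for _ in range(12)])
            cl = slope_change_likelihood(trajs, fs, kernel_sigma_min=3.0,
                                         decimate_to=None)
            uniform = 1.0 / n
            if cl.likelihood.max() < 3.0 * uniform:
                ok += 1
        assert ok >= runs * 0.75

    def test_breakpoint_exact_on_clean_kink(self):
        n = 400
        t = np.arange(n, dtype=float)
        y = np.where(t < 250, t, 250 + 0.2 * (t - 250))
        assert abs(best_breakpoint(y) - 250) <= 2


class TestEndpointsAndPercent:
    @pytest.mark.parametrize("slope,intercept,T,expected", [
        (1.0, 10.0, 0.5, (10.0, 10.5)),
        (0.0, 9.0, 2.0, (9.0, 9.0)),
    ])
    def test_endpoints(self, slope, intercept, T, expected):
        est = SlopeEstimate(slope, intercept, 0.01, 0.1, 100)
        assert endpoints_from_fit(est, T) == pytest.approx(expected)

    def test_endpoint_difference_matches_slope_times_duration(self):
        """A 2.458 a.u./hour magnitude trend over a ~25 min session moves
        the fitted endpoint by about 1.02 a.u."""
        est = SlopeEstimate(2.458, 10.0, 0.001, 0.1, 1000)
        lo, hi = endpoints_from_fit(est, 25.0 / 60.0)
        assert hi - lo == pytest.approx(1.024, abs=0.01)

    def _map_from(self, slopes, flags):
        labels = [f"c{i}" for i in range(len(slopes))]
        ests = [SlopeEstimate(s, 0.0, 0.01, 0.1, 100) for s in slopes]
        from oscitrack import SlopeMap

        return SlopeMap(labels=labels, estimates=ests,
                        flags=np.asarray(flags, dtype=bool),
                        p_adjusted=np.full(len(slopes), 0.01))

    def test_percent_positive_counts(self):
        maps = [self._map_from([1.0, -1.0], [True, True]) for _ in range(5)]
        pct = percent_positive(maps)
        assert pct["c0"] == 100.0 and pct["c1"] == 0.0
        maps3 = ([self._map_from([1.0, 1.0], [True, True])] * 3
                 + [self._map_from([1.0, 1.0], [False, True])] * 2)
        pct = percent_positive(maps3)
        assert pct["c0"] == 60.0 and pct["c1"] == 100.0

    def test_channel_mismatch_reported(self):
        m1 = self._map_from([1.0, 2.0], [True, True])
        m2 = self._map_from([1.0, 2.0, 3.0], [True, True, True])
        with pytest.raises(ValueError, match="c2"):
            percent_positive([m1, m2])


class TestSlopeMapConstruction:
    def test_flags_only_where_fdr_survives(self):
        fs = 4.0
        n = int(600 * fs)
        t_h = np.arange(n) / fs / 3600.0
        rng = np.random.default_rng(3)
        trajs = np.vstack([
            5.0 * t_h + 0.1 * rng.standard_normal(n),    # strong trend
            0.1 * rng.standard_normal(n),                # null
        ])
        m = slope_map(trajs, fs, ["trend", "null"], decimate_to=None)
        assert m.flags[0]
        assert m.slopes[0] == pytest.approx(5.0, rel=0.05)
        flags, _ = bh_fdr(m.p_values, m.fdr_q)
        assert np.array_equal(m.flags, flags)


class TestWelchPSD:
    def test_tone_peak_location(self):
        fs = 120.0
        t = np.arange(int(30 * fs)) / fs
        f, p = welch_psd(np.cos(2 * np.pi * 10 * t), fs, window_s=5.0)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.25)

    def test_white_noise_flat_within_3db(self):
        rng = np.random.default_rng(0)
        f, p = welch_psd(rng.standard_normal(2**17), 120.0, window_s=2.0)
        m = (f >= 1) & (f <= 55)
        band = 10 * np.log10(p[m])
        assert band.max() - band.min() < 3.0

    def test_normalized_psd_integrates_to_one(self):
        rng = np.random.default_rng(1)
        f, p = welch_psd(rng.standard_normal(2**15), 120.0, window_s=2.0,
                         normalize_band=(0.5, 60.0))
        m = (f >= 0.5) & (f <= 60.0)
        assert np.trapezoid(p[m], f[m]) == pytest.approx(1.0, rel=1e-9)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), 120.0, window_s=5.0)


class TestBandGridSlopes:
    def test_grid_structure_and_alpha_cell_sign(self):
        """Cells with f_min >= f_max stay NaN; the cell covering a drifting
        10 Hz rhythm carries the imposed positive slope sign (analytic-
        signal tracker, tiny grid for speed)."""
        from oscitrack import SyntheticConfig, generate_dataset
        from oscitrack.trends import band_grid_slopes

        ds = generate_dataset(SyntheticConfig(
            n_channels=2, duration=300.0, seed=4, store_trajectories=False,
            freq_jitter_sd=0.05, amp_jitter_sd=0.1,
            freq_slopes=np.full(2, 1.4), mag_slopes=np.zeros(2)))
        mat = band_grid_slopes(ds.signals, f_grid=[4.0, 8.0, 13.0],
                               tracker="hilbert")
        assert np.isnan(mat.freq_slopes[np.tril_indices(3)]).all()
        alpha_cell = mat.freq_slopes[1, 2]      # [8, 13] Hz
        assert np.isfinite(alpha_cell) and alpha_cell > 0
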