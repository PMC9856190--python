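"""Fluorescence removal, trough-baseline band integration, classification
and normalization."""

import numpy as np
import pytest

from polraman.preprocess import (
    BandWindow,
    DegenerateSpectrumError,
    band_area,
    band_measure,
    classify_component,
    normalize_reference,
    peak_height,
    preprocess_series,
    remove_baseline,
)
from polraman.profiles import default_profile
from polraman.spectra import Spectrum, WavenumberGrid
from polraman.synth import lineshape, synth_point


def make_spectrum(grid, y, **kw):
    return Spectrum(grid=grid, intensities=y, **kw)


def gaussian(w, center, sigma, amp=1.0):
    return amp * np.exp(-0.5 * ((w - center) / sigma) ** 2)


class TestRemoveBaseline:
    def test_zero_spectrum_converges_immediately(self, grid):
        res = remove_baseline(make_spectrum(grid, np.zeros(grid.n_channels)))
        assert res.converged
        assert res.n_iterations == 1
        np.testing.assert_allclose(res.corrected.intensities, 0.0)
        np.testing.assert_allclose(res.baseline, 0.0, atol=1e-12)

    def test_pure_quadratic_removed_exactly(self, grid):
        w = grid.wavenumbers
        y = 1e-4 * (w - 800.0) ** 2 + 3.0
        res = remove_baseline(make_spectrum(grid, y), poly_order=5)
        assert res.converged
        assert np.abs(res.corrected.intensities).max() < 1e-6 * y.max()

    def test_gaussian_band_survives_quadratic_background(self, grid):
        """Recovered band area within 5% of A*sigma*sqrt(2*pi)."""
        w = grid.wavenumbers
        sigma, amp = 5.0, 2.0
        y = gaussian(w, 1200.0, sigma, amp) + 1e-5 * (w - 600.0) ** 2 + 1.0
        res = remove_baseline(make_spectrum(grid, y))
        area = band_area(res.corrected, BandWindow(1200.0, 20.0))
        assert area == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.05)

    def test_near_idempotent(self, grid, rng):
        w = grid.wavenumbers
        y = gaussian(w, 1000, 6, 1.5) + gaussian(w, 1500, 8, 1.0) + 5 + 0.002 * w
        first = remove_baseline(make_spectrum(grid, y), tol=1e-4)
        second = remove_baseline(first.corrected, tol=1e-4)
        delta = np.abs(second.corrected.intensities - first.corrected.intensities)
        assert delta.max() < 1e-3 * np.abs(y).max()

    def test_rejects_nonfinite_and_bad_params(self, grid):
        y = np.zeros(grid.n_channels)
        with pytest.raises(ValueError):
            remove_baseline(make_spectrum(grid, y), poly_order=0)
        with pytest.raises(ValueError):
            remove_baseline(make_spectrum(grid, y), tol=0.0)
        bad = y.copy()
        bad[5] = np.nan
        with pytest.raises(ValueError):
            Spectrum(grid=grid, intensities=bad)


class TestBandMeasure:
    def test_flat_zero_segment(self, grid):
        m = band_measure(make_spectrum(grid, np.zeros(grid.n_channels)), BandWindow(1000.0))
        assert m.area == 0.0 and m.height == 0.0

    def test_isolated_gaussian_area_and_height(self, grid):
        """sigma=5 (fwhm 11.77), amp 1 -> area 12.533, height 1 (2%)."""
        w = grid.wavenumbers
        y = gaussian(w, 1100.0, 5.0, 1.0)
        s = make_spectrum(grid, y)
        assert band_area(s, BandWindow(1100.0, 20.0)) == pytest.approx(12.533, rel=0.02)
        assert peak_height(s, BandWindow(1100.0, 20.0)) == pytest.approx(1.0, rel=0.02)

    def test_height_linearity(self, grid):
        w = grid.wavenumbers
        y = gaussian(w, 1100.0, 5.0, 0.8)
        s1 = make_spectrum(grid, y)
        s2 = make_spectrum(grid, 2 * y)
        win = BandWindow(1100.0, 20.0)
        assert peak_height(s2, win) == pytest.approx(2 * peak_height(s1, win))
        assert band_area(s2, win) == pytest.approx(2 * band_area(s1, win))

    def test_overlapping_bands_share_a_trough(self, grid):
        """Each of two overlapping bands integrates to less than its
        isolated-band area."""
        w = grid.wavenumbers
        b1 = gaussian(w, 1247.0, 8.5, 1.0)
        b2 = gaussian(w, 1269.0, 2.5, 1.0)
        pair = make_spectrum(grid, b1 + b2)
        iso1 = band_area(make_spectrum(grid, b1), BandWindow(1247.0, 12.0))
        iso2 = band_area(make_spectrum(grid, b2), BandWindow(1269.0, 12.0))
        a1 = band_area(pair, BandWindow(1247.0, 12.0))
        a2 = band_area(pair, BandWindow(1269.0, 12.0))
        assert a1 < iso1
        assert a2 < iso2

    def test_monotone_segment_flagged(self, grid):
        w = grid.wavenumbers
        s = make_spectrum(grid, (w - grid.start) / 1000.0)  # strictly rising
        m = band_measure(s, BandWindow(1000.0, 20.0))
        assert not m.ok
        assert m.area == 0.0

    def test_window_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="outside"):
            band_measure(
                make_spectrum(grid, np.zeros(grid.n_channels)), BandWindow(510.0, 20.0)
            )

    def test_matches_bruteforce_oracle(self, grid, rng):
        """Trough-baseline area equals an independent straightforward
        implementation of the same rule, exactly."""

        def oracle(spec, window):
            g = spec.grid
            y = spec.intensities
            w = g.wavenumbers
            lo = g.index_of(window.center - window.search_halfwidth)
            hi = g.index_of(window.center + window.search_halfwidth)
            blo = g.index_of(max(window.center - 2 * window.search_halfwidth, g.start))
            bhi = g.index_of(min(window.center + 2 * window.search_halfwidth, g.stop))
            pad = np.pad(y, 2, mode="edge")
            ys = np.convolve(pad, np.ones(5) / 5.0, mode="valid")
            seg = y[lo : hi + 1]
            peak = lo + int(np.argmax(seg))
            if (peak == lo and peak > blo and y[peak - 1] >= y[peak]) or (
                peak == hi and peak < bhi and y[peak + 1] >= y[peak]
            ):
                interior = [
                    i
                    for i in range(1, hi - lo)
                    if ys[lo + i] >= ys[lo + i - 1] and ys[lo + i] >= ys[lo + i + 1]
                ]
                if not interior:
                    return 0.0
                peak = lo + max(interior, key=lambda i: ys[lo + i])
            d2 = np.diff(y[blo : bhi + 1], n=2)
            noise = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)

            def walk(step, bound):
                best, best_val, i = peak, ys[peak], peak
                while i != bound:
                    i += step
                    if ys[i] < best_val:
                        best, best_val = i, ys[i]
                    elif ys[i] - best_val > 0.05 * (ys[peak] - best_val) + 2.0 * noise:
                        break
                return best

            t_lo, t_hi = walk(-1, blo), walk(+1, bhi)
            if t_lo == peak and t_hi == peak:
                return 0.0

            def tv(idx):
                return float(np.median(y[max(idx - 3, 0) : idx + 4]))

            xx = w[t_lo : t_hi + 1]
            line = np.interp(xx, [w[t_lo], w[t_hi]], [tv(t_lo), tv(t_hi)])
            return float(np.trapezoid(np.clip(y[t_lo : t_hi + 1] - line, 0, None), xx))

        w = grid.wavenumbers
        for trial in range(8):
            y = np.zeros(grid.n_channels)
            for _ in range(rng.integers(2, 6)):
                y += gaussian(
                    w,
                    rng.uniform(700, 1800),
                    rng.uniform(3, 15),
                    rng.uniform(0.2, 2.0),
                )
            y += rng.normal(0, 0.01, y.shape)
            s = make_spectrum(grid, y)
            win = BandWindow(float(rng.uniform(700, 1800)), 20.0)
            assert band_area(s, win) == oracle(s, win)


class TestClassifyAndNormalize:
    @pytest.mark.parametrize("component", ["protein", "lipid"])
    @pytest.mark.parametrize("tissue_class", ["normal", "cancerous"])
    def test_profiles_classified_correctly(self, grid, rng, component, tissue_class):
        prof = default_profile(tissue_class, component, noise_fraction=0.0)
        ser = synth_point(prof, grid, rng, jitter=False, baseline_scale_sigma=0.0)
        pre = preprocess_series(ser)
        assert pre.component_label == component

    def test_lone_ester_band_is_lipid(self, grid):
        w = grid.wavenumbers
        s = make_spectrum(grid, gaussian(w, 1745.0, 6.0, 1.0))
        assert classify_component(s) == "lipid"

    def test_normalize_identity_and_scale_invariance(self, grid):
        w = grid.wavenumbers
        y = gaussian(w, 1450.0, 8.0, 1.0) + gaussian(w, 1003.0, 5.0, 0.4)
        s = make_spectrum(grid, y)
        out = normalize_reference(s, "protein")
        # peaks at ~1 already (up to channel discretization)
        np.testing.assert_allclose(out.intensities, y, atol=1e-3)
        out7 = normalize_reference(make_spectrum(grid, 7 * y), "protein")
        np.testing.assert_allclose(out7.intensities, out.intensities, rtol=1e-12)

    def test_normalize_halves_other_bands(self, grid):
        w = grid.wavenumbers
        y = gaussian(w, 1450.0, 8.0, 2.0) + gaussian(w, 1003.0, 5.0, 0.8)
        out = normalize_reference(make_spectrum(grid, y), "protein")
        assert out.intensities[grid.index_of(1450.0)] == pytest.approx(1.0, rel=1e-3)
        assert out.intensities[grid.index_of(1003.0)] == pytest.approx(0.4, rel=5e-3)

    def test_degenerate_reference_raises(self, grid):
        s = make_spectrum(grid, np.zeros(grid.n_channels))
        with pytest.raises(DegenerateSpectrumError):
            normalize_reference(s, "protein")


class TestPipelineInvariance:
    def test_band_quantities_invariant_to_removable_background(self, grid, rng):
        """band_area/peak_height after preprocessing do not change when a
        polynomial fluorescence background is added to the raw signal."""
        prof = default_profile("normal", "protein", noise_fraction=0.0)
        base = synth_point(prof, grid, rng, jitter=False, baseline_scale_sigma=0.0)
        prof_hi = default_profile(
            "normal",
            "protein",
            noise_fraction=0.0,
            baseline_coeffs=np.array([9.0, 3.0, 2.0, 1.0, 0.5, 0.25]),
        )
        alt = synth_point(prof_hi, grid, np.random.default_rng(42), jitter=False,
                          baseline_scale_sigma=0.0)
        pa = preprocess_series(base)
        pb = preprocess_series(alt)
        for center in (1003.0, 1450.0, 1660.0):
            win = BandWindow(center, 20.0)
            a = band_area(pa.at_angle(0.0), win)
            b = band_area(pb.at_angle(0.0), win)
            assert b == pytest.approx(a, rel=0.02)
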