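"""Band-area tables, Welch t-tests and anisotropy ratio statistics."""

import numpy as np
import pytest
from scipy import stats

from polraman import bandstats
from polraman.bandstats import (
    band_area_table,
    bimodal_ratio_curve,
    hydroxyproline_ratio,
    ttest_band,
    unsaturation_ratio,
)
from polraman.spectra import Cohort, Spectrum


def gaussian(w, center, sigma, amp=1.0):
    return amp * np.exp(-0.5 * ((w - center) / sigma) ** 2)


class TestWelch:
    def test_identical_groups(self):
        t, p = ttest_band(np.array([1.0, 1.0, 1.0]), np.array([1.0, 1.0, 1.0]))
        assert (t, p) == (0.0, 1.0)

    def test_against_closed_form(self):
        """a=(1..5), b=(6..10): t = -5 exactly; p from the Welch-
        Satterthwaite formula evaluated independently."""
        a = np.arange(1.0, 6.0)
        b = np.arange(6.0, 11.0)
        t, p = ttest_band(a, b)
        # independent oracle: hand-written Welch statistic and df
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        se2 = va / na + vb / nb
        t_oracle = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p_oracle = 2.0 * stats.t.sf(abs(t_oracle), df)
        assert t == pytest.approx(t_oracle, abs=1e-9)
        assert p == pytest.approx(p_oracle, abs=1e-9)
        assert t == pytest.approx(-5.0, abs=1e-12)
        assert p == pytest.approx(0.00105, abs=5e-5)

    def test_swap_symmetry(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1.5, 9)
        t1, p1 = ttest_band(a, b)
        t2, p2 = ttest_band(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_band(np.array([1.0]), np.array([1.0, 2.0]))


class TestBandAreaTable:
    def test_single_spectrum_per_class_gives_zero_std(self, small_pre):
        one = Cohort(series=[small_pre.series[0], small_pre.series[-1]],
                     grid=small_pre.grid)
        table = band_area_table(one, small_pre.series[0].component_label)
        present = table[~table.missing]
        assert (present.std_area == 0.0).all()
        assert (present.n == 1).all()

    def test_order_invariance(self, small_pre):
        fwd = band_area_table(small_pre, "protein")
        rev = Cohort(series=list(reversed(small_pre.series)), grid=small_pre.grid)
        bwd = band_area_table(rev, "protein")
        for col in ("mean_area", "std_area", "n"):
            np.testing.assert_allclose(fwd[col].fillna(-1), bwd[col].fillna(-1))

    def test_missing_class_flagged_not_fabricated(self, small_pre):
        no_normal = small_pre.select(["cancerous"])
        table = band_area_table(no_normal, "protein")
        assert not table.missing.any()  # only the present class is tabulated
        assert set(table.tissue_class) == {"cancerous"}


class TestRatios:
    def _two_band_series(self, grid, h1247, h1269):
        from polraman.spectra import ANGLES_DEG, PolarizationSeries

        w = grid.wavenumbers
        y = gaussian(w, 1247.0, 6.0, h1247) + gaussian(w, 1269.0, 4.0, h1269)
        spectra = [
            Spectrum(grid=grid, intensities=y, polarization_deg=t) for t in ANGLES_DEG
        ]
        conv = Spectrum(grid=grid, intensities=y)
        return PolarizationSeries(spectra=spectra, conventional=conv)

    def test_equal_height_bands_give_unit_ratio(self, grid):
        ser = self._two_band_series(grid, 1.0, 1.0)
        curve = bimodal_ratio_curve(ser)
        assert curve.valid.all()
        np.testing.assert_allclose(curve.ratio, 1.0, atol=0.07)

    def test_ratio_curve_180_periodic_noise_free(self, grid, rng):
        from polraman.profiles import default_profile
        from polraman.synth import synth_point
        from polraman.preprocess import preprocess_series

        prof = default_profile("normal", "protein", noise_fraction=0.0)
        pre = preprocess_series(synth_point(prof, grid, rng, jitter=False,
                                            baseline_scale_sigma=0.0))
        curve = bimodal_ratio_curve(pre)
        np.testing.assert_allclose(curve.ratio[:6], curve.ratio[6:], rtol=1e-6)

    def test_zero_denominator_flagged(self, grid):
        ser = self._two_band_series(grid, 1.0, 0.0)
        curve = bimodal_ratio_curve(ser)
        assert not curve.valid.any()
        assert np.isnan(curve.ratio).all()

    def test_hydroxyproline_equal_areas_and_scale_invariance(self, grid):
        w = grid.wavenumbers
        y = gaussian(w, 875.0, 5.0, 1.0) + gaussian(w, 921.0, 5.0, 1.0)
        s = Spectrum(grid=grid, intensities=y)
        assert hydroxyproline_ratio(s) == pytest.approx(1.0, abs=0.02)
        s9 = Spectrum(grid=grid, intensities=9 * y)
        assert hydroxyproline_ratio(s9) == pytest.approx(hydroxyproline_ratio(s))

    def test_unsaturation_equal_heights_and_scale_invariance(self, grid):
        w = grid.wavenumbers
        y = gaussian(w, 1652.0, 8.0, 1.0) + gaussian(w, 1442.0, 8.0, 1.0)
        s = Spectrum(grid=grid, intensities=y)
        assert unsaturation_ratio(s) == pytest.approx(1.0, abs=0.02)
        s3 = Spectrum(grid=grid, intensities=3 * y)
        assert unsaturation_ratio(s3) == pytest.approx(unsaturation_ratio(s))

    def test_unsaturation_increases_with_cancerization(self, default_pre):
        means = {}
        for tc in ("normal", "cancerous"):
            vals = [
                unsaturation_ratio(s.conventional)
                for s in default_pre.series
                if s.component_label == "lipid" and s.tissue_class == tc
            ]
            means[tc] = np.nanmean(vals)
        assert means["cancerous"] > means["normal"]


class TestHydroxyprolineTable:
    def test_cancerization_raises_hydroxyproline_fraction(self, default_pre):
        table = bandstats.hydroxyproline_table(default_pre)
        conv = table[table["mode"] == "conventional"].set_index("tissue_class").ratio
        assert conv["cancerous"] > conv["normal"]
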