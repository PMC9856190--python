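"""Synthetic cohort generator: cos^2 anisotropy law, point/cohort assembly,
reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polraman.profiles import default_profile
from polraman.spectra import ANGLES_DEG, BandProfile, PolarizationSeries
from polraman.synth import (
    CohortConfig,
    band_amplitude_at_angle,
    synth_cohort,
    synth_point,
    synth_spectrum,
)


def _flat_profile(bands, noise=0.0, **kwargs):
    from polraman.spectra import TissueProfile

    return TissueProfile(
        tissue_class="normal",
        component="protein",
        bands=bands,
        baseline_coeffs=np.zeros(6),
        noise_sigma=noise,
        **kwargs,
    )


class TestAmplitudeLaw:
    @pytest.mark.parametrize(
        "band, theta, expected",
        [
            (BandProfile(1000, 10, a_iso=0.7, a_aniso=0.0), 123.0, 0.7),
            (BandProfile(1000, 10, a_iso=0.2, a_aniso=0.5, orientation_deg=40.0), 40.0, 0.7),
            (BandProfile(1000, 10, a_iso=1.0, a_aniso=2.0, orientation_deg=0.0), 60.0, 1.5),
        ],
    )
    def test_examples(self, band, theta, expected):
        assert band_amplitude_at_angle(band, theta) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        theta=st.floats(0.0, 360.0, allow_nan=False),
        a_iso=st.floats(0.0, 5.0),
        a_aniso=st.floats(0.0, 5.0),
        phi=st.floats(0.0, 180.0),
    )
    def test_quarter_turn_identity(self, theta, a_iso, a_aniso, phi):
        """A(theta) + A(theta+90°) = 2*a_iso + a_aniso, exactly (cos^2 law)."""
        band = BandProfile(1000, 10, a_iso=a_iso, a_aniso=a_aniso, orientation_deg=phi)
        total = band_amplitude_at_angle(band, theta) + band_amplitude_at_angle(
            band, theta + 90.0
        )
        assert total == pytest.approx(2 * a_iso + a_aniso, abs=1e-9)

    def test_half_turn_periodic(self):
        band = BandProfile(1000, 10, a_iso=0.3, a_aniso=1.1, orientation_deg=25.0)
        for theta in ANGLES_DEG:
            assert band_amplitude_at_angle(band, theta) == pytest.approx(
                band_amplitude_at_angle(band, theta + 180.0)
            )

    def test_conventional_is_circular_mean_of_12_angles(self):
        band = BandProfile(1000, 10, a_iso=0.4, a_aniso=0.9, orientation_deg=37.0)
        mean12 = np.mean([band_amplitude_at_angle(band, t) for t in ANGLES_DEG])
        assert band_amplitude_at_angle(band, None) == pytest.approx(mean12, abs=1e-12)


class TestSynthSpectrum:
    def test_empty_profile_gives_zero_spectrum(self, grid):
        prof = _flat_profile([])
        s = synth_spectrum(prof, 0.0, grid)
        assert np.all(s.intensities == 0.0)

    def test_single_gaussian_peak_position_and_height(self, grid):
        prof = _flat_profile([BandProfile(1003.0, 12.0, a_iso=2.5)])
        s = synth_spectrum(prof, 0.0, grid)
        peak = int(np.argmax(s.intensities))
        assert peak == grid.index_of(1003.0)
        # nearest channel sits up to ~0.4 cm^-1 off-center
        assert s.intensities[peak] == pytest.approx(2.5, rel=5e-3)

    def test_band_outside_grid_rejected(self, grid):
        prof = _flat_profile([BandProfile(3000.0, 12.0, a_iso=1.0)])
        with pytest.raises(ValueError, match="outside the grid"):
            synth_spectrum(prof, 0.0, grid)

    def test_noise_requires_rng(self, grid):
        prof = _flat_profile([BandProfile(1003.0, 12.0, a_iso=1.0)], noise=0.1)
        with pytest.raises(ValueError, match="rng"):
            synth_spectrum(prof, 0.0, grid)


class TestSynthPoint:
    def test_series_invariants_and_angle_symmetry(self, grid, rng):
        prof = default_profile("normal", "protein", noise_fraction=0.0)
        ser = synth_point(prof, grid, rng, jitter=False)
        assert isinstance(ser, PolarizationSeries)
        assert [s.polarization_deg for s in ser.spectra] == list(ANGLES_DEG)
        # 180° periodicity of the cos^2 law, noise off
        for theta in (0.0, 30.0, 60.0, 90.0, 120.0, 150.0):
            np.testing.assert_allclose(
                ser.at_angle(theta).intensities,
                ser.at_angle(theta + 180.0).intensities,
            )

    def test_conventional_equals_angular_mean(self, grid, rng):
        prof = default_profile("cancerous", "lipid", noise_fraction=0.0)
        ser = synth_point(prof, grid, rng, jitter=True)
        np.testing.assert_allclose(
            ser.conventional.intensities, ser.stack().mean(axis=0), atol=1e-12
        )

    def test_deterministic_under_seed(self, grid):
        prof = default_profile("normal", "lipid")
        a = synth_point(prof, grid, np.random.default_rng(5))
        b = synth_point(prof, grid, np.random.default_rng(5))
        np.testing.assert_array_equal(a.stack(), b.stack())
        np.testing.assert_array_equal(
            a.conventional.intensities, b.conventional.intensities
        )


class TestSynthCohort:
    def test_default_census(self, default_cohort):
        """Study layout: 42 samples (20+10+12), 10 points each."""
        samples = default_cohort.sample_table()
        assert len(samples) == 42
        assert len(default_cohort) == 420
        by_class = {}
        for s in samples:
            by_class[s["tissue_class"]] = by_class.get(s["tissue_class"], 0) + 1
        assert by_class == {"cancerous": 20, "normal": 10, "paracancerous": 12}

    def test_small_config_arithmetic(self):
        cfg = CohortConfig(n_cancerous=1, n_normal=1, n_paracancerous=0, points_per_sample=2)
        cohort = synth_cohort(cfg, seed=0)
        assert len(cohort) == 4  # 2 samples x 2 points

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_cancerous=0)
        with pytest.raises(ValueError):
            CohortConfig(n_cancerous=2, n_normal=5)
        with pytest.raises(ValueError):
            CohortConfig(points_per_sample=0)

    def test_bit_reproducible(self):
        cfg = CohortConfig(n_cancerous=2, n_normal=1, n_paracancerous=1, points_per_sample=2)
        a = synth_cohort(cfg, seed=3)
        b = synth_cohort(cfg, seed=3)
        for sa, sb in zip(a.series, b.series):
            np.testing.assert_array_equal(sa.stack(), sb.stack())

    def test_intensities_nonnegative(self, default_cohort):
        for ser in default_cohort.series[::37]:
            assert ser.stack().min() >= 0.0
            assert ser.conventional.intensities.min() >= 0.0

    def test_normal_patients_share_cancerous_patient_ids(self, default_cohort):
        samples = default_cohort.sample_table()
        cancer_patients = {s["patient_id"] for s in samples if s["tissue_class"] == "cancerous"}
        normal_patients = {s["patient_id"] for s in samples if s["tissue_class"] == "normal"}
        assert normal_patients <= cancer_patients
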