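"""Synthetic polarized Raman cohort generator.

Emulates a polarized micro-Raman acquisition of excised breast tissue:
for each detection point, 12 spectra at linear polarization angles
0°,30°,...,330° plus one conventional spectrum.  Band intensities follow
a Malus-type cos^2 law; points are a mixture of protein-dominated and
lipid-dominated spectra; a broad fluorescence background and truncated
Gaussian channel noise are added on top.

The default cohort mirrors the study layout: 20 cancerous, 10 normal and
12 paracancerous samples from 20 patients (every patient contributes a
cancerous sample; the first 10 also contribute a normal sample, the
first 12 a paracancerous one), 10 detection points per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import default_profiles
from .spectra import (
    ANGLES_DEG,
    BandProfile,
    Cohort,
    PolarizationSeries,
    Spectrum,
    TissueProfile,
    WavenumberGrid,
)

__all__ = [
    "CohortConfig",
    "band_amplitude_at_angle",
    "lineshape",
    "synth_spectrum",
    "synth_point",
    "synth_cohort",
]


@dataclass
class CohortConfig:
    """Cohort layout and generator knobs."""

    n_cancerous: int = 20
    n_normal: int = 10
    n_paracancerous: int = 12
    points_per_sample: int = 10
    protein_fraction: float = 0.5  # fraction of points with protein-type spectra
    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    profiles: dict | None = None  # (tissue_class, component) -> TissueProfile
    baseline_scale_sigma: float = 0.2  # lognormal sigma of per-point background
    jitter: bool = True  # per-point band-amplitude spread

    def __post_init__(self) -> None:
        if self.n_cancerous <= 0 or self.n_normal < 0 or self.n_paracancerous < 0:
            raise ValueError("sample counts must be positive (cancerous) / non-negative")
        if self.n_normal > self.n_cancerous or self.n_paracancerous > self.n_cancerous:
            raise ValueError(
                "normal/paracancerous counts cannot exceed the patient count "
                "(every patient contributes a cancerous sample)"
            )
        if self.points_per_sample <= 0:
            raise ValueError("points_per_sample must be positive")
        if not (0.0 <= self.protein_fraction <= 1.0):
            raise ValueError("protein_fraction must lie in [0, 1]")


def band_amplitude_at_angle(band: BandProfile, theta_deg: float) -> float:
    """Band amplitude under linear polarization at ``theta_deg``.

    A(theta) = a_iso + a_aniso * cos^2(theta - orientation); 180°-periodic.
    ``theta_deg=None`` gives the conventional (angle-averaged) amplitude
    a_iso + a_aniso/2, the circular mean of the cos^2 law.
    """
    if theta_deg is None:
        return band.a_iso + 0.5 * band.a_aniso
    c = np.cos(np.deg2rad(theta_deg - band.orientation_deg))
    return band.a_iso + band.a_aniso * c * c


def lineshape(
    wavenumbers: np.ndarray, center: float, fwhm: float, shape_mix: float = 1.0
) -> np.ndarray:
    """Unit-height pseudo-Voigt profile (shape_mix = Gaussian fraction)."""
    dx = wavenumbers - center
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gauss = np.exp(-0.5 * (dx / sigma) ** 2)
    gamma = fwhm / 2.0
    lorentz = gamma**2 / (dx**2 + gamma**2)
    return shape_mix * gauss + (1.0 - shape_mix) * lorentz


def _baseline(grid: WavenumberGrid, coeffs: np.ndarray) -> np.ndarray:
    x = (grid.wavenumbers - grid.start) / (grid.stop - grid.start)
    return np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))


def synth_spectrum(
    profile: TissueProfile,
    theta_deg: float | None,
    grid: WavenumberGrid,
    rng: np.random.Generator | None = None,
    band_scales: np.ndarray | None = None,
    band_shifts: np.ndarray | None = None,
    baseline_scale: float = 1.0,
    **metadata,
) -> Spectrum:
    """One synthetic spectrum at angle ``theta_deg`` (None = conventional).

    ``band_scales`` and ``band_shifts`` are per-band multiplicative
    amplitude factors and additive center offsets in cm^-1 (drawn per
    detection point, shared by all 13 spectra of that point);
    ``baseline_scale`` scales the fluorescence background likewise.
    Channel noise is i.i.d. Gaussian and the final intensities are
    truncated at zero.
    """
    for b in profile.bands:
        if not (grid.start <= b.center <= grid.stop):
            raise ValueError(
                f"band at {b.center} cm^-1 falls outside the grid "
                f"[{grid.start}, {grid.stop}]"
            )
    w = grid.wavenumbers
    y = np.zeros(grid.n_channels)
    if band_scales is None:
        band_scales = np.ones(len(profile.bands))
    if band_shifts is None:
        band_shifts = np.zeros(len(profile.bands))
    for b, scale, shift in zip(profile.bands, band_scales, band_shifts):
        amp = band_amplitude_at_angle(b, theta_deg) * scale
        if amp != 0.0:
            y += amp * lineshape(w, b.center + shift, b.fwhm, b.shape_mix)
    y += baseline_scale * _baseline(grid, profile.baseline_coeffs)
    if profile.noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        y = y + rng.normal(0.0, profile.noise_sigma, size=y.shape)
    np.clip(y, 0.0, None, out=y)
    return Spectrum(
        grid=grid,
        intensities=y,
        tissue_class=profile.tissue_class,
        component=profile.component,
        polarization_deg=theta_deg,
        **metadata,
    )


def synth_point(
    profile: TissueProfile,
    grid: WavenumberGrid,
    rng: np.random.Generator,
    jitter: bool = True,
    baseline_scale_sigma: float = 0.0,
    **metadata,
) -> PolarizationSeries:
    """One detection point: 12 polarized spectra plus one conventional.

    The per-point band-amplitude jitter and background scale are drawn
    once and shared by all 13 spectra (they model tissue heterogeneity
    between points, not acquisition noise), so that with noise off the
    conventional spectrum is exactly the angular mean of the stack.
    """
    if jitter:
        sig = np.array([b.rel_jitter for b in profile.bands])
        band_scales = np.exp(rng.normal(-0.5 * sig**2, sig))
        csig = np.array([b.center_jitter for b in profile.bands])
        band_shifts = rng.normal(0.0, 1.0, len(profile.bands)) * csig
    else:
        band_scales = np.ones(len(profile.bands))
        band_shifts = np.zeros(len(profile.bands))
    if baseline_scale_sigma > 0:
        baseline_scale = float(np.exp(rng.normal(0.0, baseline_scale_sigma)))
    else:
        baseline_scale = 1.0
    spectra = [
        synth_spectrum(
            profile, theta, grid, rng,
            band_scales=band_scales, band_shifts=band_shifts,
            baseline_scale=baseline_scale, **metadata,
        )
        for theta in ANGLES_DEG
    ]
    conventional = synth_spectrum(
        profile, None, grid, rng,
        band_scales=band_scales, band_shifts=band_shifts,
        baseline_scale=baseline_scale, **metadata,
    )
    return PolarizationSeries(spectra=spectra, conventional=conventional)


def synth_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Generate a full synthetic cohort (bit-reproducible for a given seed).

    Patients are labelled p01..pN (N = n_cancerous); sample ids encode
    patient and tissue class.  Within each sample the first
    round(protein_fraction * points) detection points carry protein-type
    spectra, the rest lipid-type.
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(seed)
    profiles = config.profiles if config.profiles is not None else default_profiles()

    samples: list[tuple[str, str, str]] = []  # (sample_id, patient_id, class)
    for i in range(config.n_cancerous):
        pid = f"p{i + 1:02d}"
        samples.append((f"{pid}_cancerous", pid, "cancerous"))
    for i in range(config.n_normal):
        pid = f"p{i + 1:02d}"
        samples.append((f"{pid}_normal", pid, "normal"))
    for i in range(config.n_paracancerous):
        pid = f"p{i + 1:02d}"
        samples.append((f"{pid}_paracancerous", pid, "paracancerous"))

    n_protein = int(round(config.protein_fraction * config.points_per_sample))
    series: list[PolarizationSeries] = []
    for sample_id, patient_id, tissue_class in samples:
        for point in range(config.points_per_sample):
            component = "protein" if point < n_protein else "lipid"
            profile = profiles[(tissue_class, component)]
            series.append(
                synth_point(
                    profile,
                    config.grid,
                    rng,
                    jitter=config.jitter,
                    baseline_scale_sigma=config.baseline_scale_sigma,
                    patient_id=patient_id,
                    sample_id=sample_id,
                    point_index=point,
                )
            )
    return Cohort(series=series, grid=config.grid, seed=seed)
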