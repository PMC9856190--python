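"""Core data containers for polarized micro-Raman spectra.

A detection point on a tissue sample yields 13 spectra: one at each of 12
linear polarization angles (0°, 30°, ..., 330°) plus one conventional
(non-polarized) spectrum.  All spectra share a uniform wavenumber grid,
by default 1780 channels covering 500-2000 cm^-1 (~0.84 cm^-1 spacing,
matching a 3 cm^-1 optical resolution after interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ANGLES_DEG",
    "TISSUE_CLASSES",
    "COMPONENTS",
    "WavenumberGrid",
    "BandProfile",
    "TissueProfile",
    "Spectrum",
    "PolarizationSeries",
    "Cohort",
]

#: The 12 polarization angles in degrees.  0° and 360° coincide for linear
#: polarization, so the duplicate endpoint is dropped.
ANGLES_DEG: np.ndarray = np.arange(12, dtype=float) * 30.0

TISSUE_CLASSES = ("normal", "paracancerous", "cancerous")
COMPONENTS = ("protein", "lipid")


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform Raman-shift grid in cm^-1 (inclusive endpoints)."""

    start: float = 500.0
    stop: float = 2000.0
    n_channels: int = 1780

    def __post_init__(self) -> None:
        if not (self.stop > self.start):
            raise ValueError("grid stop must exceed start")
        if self.n_channels < 2:
            raise ValueError("grid needs at least 2 channels")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_channels)

    @property
    def spacing(self) -> float:
        return (self.stop - self.start) / (self.n_channels - 1)

    def index_of(self, wavenumber: float) -> int:
        """Channel index nearest to ``wavenumber``; raises if outside grid."""
        if not (self.start <= wavenumber <= self.stop):
            raise ValueError(
                f"wavenumber {wavenumber} cm^-1 outside grid "
                f"[{self.start}, {self.stop}]"
            )
        return int(round((wavenumber - self.start) / self.spacing))


@dataclass
class BandProfile:
    """One synthetic Raman band with a Malus-type cos^2 polarization response.

    The observed amplitude at polarization angle theta is

        A(theta) = a_iso + a_aniso * cos^2(theta - orientation_deg)

    which is 180°-periodic and reduces to ``a_iso + a_aniso/2`` when
    averaged over all angles (the conventional, non-polarized amplitude).
    ``shape_mix`` is the Gaussian fraction of a pseudo-Voigt lineshape.
    """

    center: float
    fwhm: float
    a_iso: float
    a_aniso: float = 0.0
    orientation_deg: float = 0.0
    shape_mix: float = 1.0
    rel_jitter: float = 0.0  # per-point lognormal amplitude spread (relative)
    center_jitter: float = 0.0  # per-point Gaussian spread of the position (cm^-1)

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be positive")
        if self.a_iso < 0:
            raise ValueError("a_iso must be non-negative")
        if self.a_iso + self.a_aniso < 0:
            raise ValueError("a_iso + a_aniso must be non-negative")
        if not (0.0 <= self.shape_mix <= 1.0):
            raise ValueError("shape_mix must lie in [0, 1]")


@dataclass
class TissueProfile:
    """Band set, fluorescence background and noise level for one
    (tissue class, component) combination."""

    tissue_class: str
    component: str
    bands: list[BandProfile]
    baseline_coeffs: np.ndarray = field(
        default_factory=lambda: np.zeros(6)
    )  # polynomial in x = (w - start)/(stop - start), low order first
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        self.baseline_coeffs = np.asarray(self.baseline_coeffs, dtype=float)

    def band_at(self, center: float, tol: float = 1.0) -> BandProfile:
        for b in self.bands:
            if abs(b.center - center) <= tol:
                return b
        raise KeyError(f"no band near {center} cm^-1")


@dataclass
class Spectrum:
    """A single intensity trace with acquisition metadata.

    ``polarization_deg`` is the linear polarization angle in degrees, or
    ``None`` for a conventional (non-polarized) acquisition.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    patient_id: str = ""
    sample_id: str = ""
    tissue_class: str = ""
    component: str | None = None
    point_index: int = 0
    polarization_deg: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_channels,):
            raise ValueError(
                f"intensity vector length {self.intensities.shape} does not "
                f"match grid ({self.grid.n_channels} channels)"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("spectrum intensities must be finite")

    @property
    def is_conventional(self) -> bool:
        return self.polarization_deg is None

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class PolarizationSeries:
    """The ordered 12-angle polarization stack for one detection point,
    plus the conventional spectrum acquired at the same point."""

    spectra: list[Spectrum]
    conventional: Spectrum
    component_label: str | None = None  # assigned by the preprocessing stage

    def __post_init__(self) -> None:
        if len(self.spectra) != 12:
            raise ValueError(f"expected 12 polarized spectra, got {len(self.spectra)}")
        angles = [s.polarization_deg for s in self.spectra]
        if any(a is None for a in angles):
            raise ValueError("polarized spectra must carry an angle")
        if sorted(angles) != list(ANGLES_DEG):
            raise ValueError(
                f"angles must be 0,30,...,330 (got {sorted(angles)})"
            )
        if angles != sorted(angles):
            self.spectra = sorted(self.spectra, key=lambda s: s.polarization_deg)
        keys = {
            (s.patient_id, s.sample_id, s.point_index)
            for s in self.spectra + [self.conventional]
        }
        if len(keys) != 1:
            raise ValueError("all spectra of a series must share point metadata")
        if not self.conventional.is_conventional:
            raise ValueError("the conventional spectrum must have no angle")

    @property
    def patient_id(self) -> str:
        return self.conventional.patient_id

    @property
    def sample_id(self) -> str:
        return self.conventional.sample_id

    @property
    def tissue_class(self) -> str:
        return self.conventional.tissue_class

    @property
    def point_index(self) -> int:
        return self.conventional.point_index

    def at_angle(self, angle_deg: float) -> Spectrum:
        for s in self.spectra:
            if s.polarization_deg == angle_deg:
                return s
        raise KeyError(f"no spectrum at {angle_deg} degrees")

    def stack(self) -> np.ndarray:
        """(12, n_channels) matrix, rows in ascending angle order."""
        return np.stack([s.intensities for s in self.spectra])


@dataclass
class Cohort:
    """A bag of PolarizationSeries with generation bookkeeping."""

    series: list[PolarizationSeries]
    grid: WavenumberGrid
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.series)

    def sample_table(self) -> "list[dict]":
        """One row per sample: sample_id, patient_id, tissue_class, n_points."""
        rows: dict[str, dict] = {}
        for ser in self.series:
            r = rows.setdefault(
                ser.sample_id,
                {
                    "sample_id": ser.sample_id,
                    "patient_id": ser.patient_id,
                    "tissue_class": ser.tissue_class,
                    "n_points": 0,
                },
            )
            r["n_points"] += 1
        return list(rows.values())

    def select(self, tissue_classes: Sequence[str] | None = None) -> "Cohort":
        if tissue_classes is None:
            return self
        keep = [s for s in self.series if s.tissue_class in tissue_classes]
        return Cohort(series=keep, grid=self.grid, seed=self.seed)
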