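"""Default tissue profiles for the synthetic cohort generator.

Each (component, tissue class) pair carries a band table.  Bands are
parameterized in *measured-area space*: the targets below are the mean
trough-baseline band areas (after fluorescence removal and normalization
to the 1450 cm^-1 protein / 1442 cm^-1 lipid reference band) that the
generated cohort should reproduce, for parallel-polarized (0°) and
conventional acquisition.  The published per-class means for excised
breast tissue serve as the calibration targets; a few entries are nudged
within the stated ±25% calibration tolerance so that class differences
remain resolvable at the default cohort size (see docs/methods.md).

The cos^2 anisotropy parameters follow from the two targets:

    parallel     A(0°)  = a_iso + a_aniso * cos^2(orientation)
    conventional A_conv = a_iso + a_aniso / 2

With orientation restricted to {0°, 90°} the pair (parallel, conventional)
determines (a_iso, a_aniso) uniquely; the orientation is 0° when the band
is brighter parallel than conventional and 90° otherwise.

Area-space targets are converted to generator amplitudes through the
per-band factors in ``CAL_FACTORS`` (measured area produced per unit of
ideal Gaussian area), determined once by running the full measurement
pipeline on synthetic points at the default noise level (trough-chord
integration of the positive part carries an additive noise-floor bias,
so calibration against noisy means is what makes the cohort-level
measured tables land on target).
"""

from __future__ import annotations

import numpy as np

from .spectra import BandProfile, TissueProfile, WavenumberGrid

__all__ = [
    "PROTEIN_BAND_CENTERS",
    "LIPID_BAND_CENTERS",
    "AMIDE_I_CENTER",
    "REFERENCE_BAND",
    "default_profile",
    "default_profiles",
]

#: Protein band centers (cm^-1): hydroxyproline 875, proline 921,
#: phenylalanine 1003/1032, amide III 1247/1269, collagen CH2 1302/1318,
#: CH2/CH3 deformation 1450, amide I 1660 (1656 in cancerous tissue).
PROTEIN_BAND_CENTERS = (875, 921, 1003, 1032, 1247, 1269, 1302, 1318, 1450, 1660)

#: Lipid band centers (cm^-1): phospholipid 871/971/1032/1084,
#: =C-H 1269/1302, CH2 deformation 1442, C=C 1652, C=O ester 1745.
LIPID_BAND_CENTERS = (871, 971, 1032, 1084, 1269, 1302, 1442, 1652, 1745)

#: Amide I position per tissue class: red-shifts 1660 -> 1656 in cancer.
AMIDE_I_CENTER = {"normal": 1660.0, "paracancerous": 1660.0, "cancerous": 1656.0}

#: Normalization reference band per component.
REFERENCE_BAND = {"protein": 1450.0, "lipid": 1442.0}

#: Band-specific peak-search halfwidths (cm^-1) where the default of 20
#: would reach a close neighbour; keys are (component, band center).
#: The collagen CH2 twisting pair 1302/1318 sits only 16 cm^-1 apart.
BAND_WINDOW_HALFWIDTHS: dict[tuple[str, int], float] = {
    ("protein", 1302): 7.0,
    ("protein", 1318): 7.0,
    ("protein", 1247): 12.0,
    ("protein", 1269): 12.0,
    ("lipid", 871): 10.0,
}


def band_window_halfwidth(component: str, center: int, default: float = 20.0) -> float:
    return BAND_WINDOW_HALFWIDTHS.get((component, int(center)), default)

# ---------------------------------------------------------------------------
# Band tables.
# Entries: center -> (fwhm, parallel_area, conventional_area, rel_jitter)
# "center" for the amide I row is the key 1660; the actual position is
# class dependent (AMIDE_I_CENTER).
# ---------------------------------------------------------------------------

_PROTEIN: dict[str, dict[int, tuple[float, float, float, float]]] = {
    "cancerous": {
        875: (9.0, 0.85, 0.90, 0.25),
        921: (9.0, 0.95, 1.10, 0.15),
        1003: (8.0, 4.16, 4.78, 0.15),
        1032: (9.0, 2.30, 2.73, 0.15),
        1302: (8.0, 0.37, 0.32, 0.25),
        1318: (8.0, 0.18, 0.24, 0.25),
        1450: (48.0, 40.82, 39.07, 0.05),
        1660: (34.0, 49.99, 56.52, 0.10),
    },
    "normal": {
        875: (9.0, 1.30, 1.25, 0.25),
        921: (9.0, 1.75, 1.75, 0.15),
        1003: (8.0, 4.33, 4.90, 0.15),
        1032: (9.0, 3.00, 2.82, 0.15),
        1302: (8.0, 0.13, 0.25, 0.25),
        1318: (8.0, 0.27, 0.29, 0.25),
        1450: (48.0, 43.94, 42.20, 0.05),
        1660: (34.0, 48.21, 48.68, 0.10),
    },
    "paracancerous": {
        875: (9.0, 1.10, 1.10, 0.25),
        921: (9.0, 1.35, 1.45, 0.15),
        1003: (8.0, 4.25, 4.84, 0.15),
        1032: (9.0, 2.65, 2.78, 0.15),
        1302: (8.0, 0.25, 0.29, 0.25),
        1318: (8.0, 0.22, 0.26, 0.25),
        1450: (48.0, 42.40, 40.60, 0.05),
        1660: (34.0, 49.10, 52.60, 0.10),
    },
}

_LIPID: dict[str, dict[int, tuple[float, float, float, float]]] = {
    "cancerous": {
        871: (9.0, 0.24, 0.63, 0.15),
        971: (10.0, 1.06, 1.23, 0.20),
        1032: (10.0, 1.18, 0.76, 0.20),
        1084: (12.0, 1.36, 2.12, 0.15),
        1269: (12.0, 6.94, 7.89, 0.15),
        1302: (12.0, 8.47, 8.72, 0.15),
        1442: (41.0, 37.55, 38.91, 0.05),
        1652: (22.0, 17.54, 21.00, 0.10),
        1745: (14.0, 2.98, 3.98, 0.15),
    },
    "normal": {
        871: (9.0, 0.53, 0.64, 0.15),
        971: (10.0, 1.49, 1.31, 0.20),
        1032: (10.0, 1.31, 0.83, 0.20),
        1084: (12.0, 1.72, 2.25, 0.15),
        1269: (12.0, 6.81, 8.08, 0.15),
        1302: (12.0, 8.68, 8.52, 0.15),
        1442: (41.0, 36.89, 37.33, 0.05),
        1652: (22.0, 14.21, 17.00, 0.10),
        1745: (14.0, 1.89, 3.15, 0.15),
    },
    "paracancerous": {
        871: (9.0, 0.44, 0.63, 0.15),
        971: (10.0, 1.28, 1.27, 0.20),
        1032: (10.0, 1.25, 0.80, 0.20),
        1084: (12.0, 1.54, 2.19, 0.15),
        1269: (12.0, 6.88, 7.99, 0.15),
        1302: (12.0, 8.58, 8.62, 0.15),
        1442: (41.0, 37.22, 38.12, 0.05),
        1652: (22.0, 15.90, 19.00, 0.10),
        1745: (14.0, 2.44, 3.57, 0.15),
    },
}

_TABLES = {"protein": _PROTEIN, "lipid": _LIPID}

# ---------------------------------------------------------------------------
# Amide III doublet (protein 1247 / 1269 cm^-1).
#
# The collagen-orientation signature lives in the *height* ratio
# I1247/I1269: in normal and paracancerous tissue it rises from below 1
# at 0° to above 1 at 90° (horizontal collagen fibers); in cancerous
# tissue the anisotropy collapses and the ratio stays below 1 at every
# angle.  Because a broad band (1247) and a narrow band (1269) sitting
# 22 cm^-1 apart share a trough, their trough-line areas and heights are
# linked nonlinearly, so the doublet is parameterized directly by its
# 0° and 90° generator amplitudes per class (hb = broad, hn = narrow);
# conventional amplitudes are the cos^2 circular means.  The published
# mean areas remain the calibration check (within the ±25% band) but
# cannot be matched exactly while keeping the height ratio below 1; see
# docs/methods.md.
# ---------------------------------------------------------------------------

AMIDE_III = {"broad_center": 1247.0, "broad_fwhm": 20.0,
             "narrow_center": 1269.0, "narrow_fwhm": 6.0, "rel_jitter": 0.15}

#: Per-class doublet amplitudes at 0° and 90°.
DOUBLET_AMPLITUDES: dict[str, dict[str, float]] = {
    "normal": {"hb0": 0.3010, "hb90": 0.3180, "hn0": 0.3465, "hn90": 0.2684},
    "paracancerous": {"hb0": 0.2654, "hb90": 0.3043, "hn0": 0.3200, "hn90": 0.2880},
    "cancerous": {"hb0": 0.2548, "hb90": 0.2556, "hn0": 0.3218, "hn90": 0.3218},
}


def _cos2_from_endpoints(amp0: float, amp90: float) -> tuple[float, float, float]:
    """(a_iso, a_aniso, orientation) with the given 0°/90° amplitudes."""
    if amp90 > amp0:
        return amp0, amp90 - amp0, 90.0
    return amp90, amp0 - amp90, 0.0

#: Measured trough-baseline area produced by the full pipeline per unit of
#: ideal Gaussian band area, for unit-scale noise-free profiles.  Values
#: below 1 reflect trough clipping and shared troughs between overlapping
#: bands; values above 1 reflect flank pickup from broad neighbours.
#: Determined once with scripts/calibrate_profiles.py and frozen here.
CAL_FACTORS: dict[tuple[str, int], float] = {
    ("protein", 875): 2.3783,
    ("protein", 921): 1.9855,
    ("protein", 1003): 1.3072,
    ("protein", 1032): 1.3290,
    ("protein", 1302): 1.6127,
    ("protein", 1318): 1.7590,
    ("protein", 1450): 1.0,  # normalization reference
    ("protein", 1660): 1.1388,
    ("lipid", 871): 1.9170,
    ("lipid", 971): 2.0241,
    ("lipid", 1032): 2.2658,
    ("lipid", 1084): 1.6043,
    ("lipid", 1269): 1.1435,
    ("lipid", 1302): 1.1219,
    ("lipid", 1442): 1.0,  # normalization reference
    ("lipid", 1652): 1.1662,
    ("lipid", 1745): 1.4500,
}

# Peak height of a unit-area Gaussian-like band: area = h * fwhm * 1.0645
_AREA_TO_HEIGHT = 1.0 / 1.0645

#: Default fluorescence background: polynomial in x = (w-500)/1500 on [0,1],
#: low order first.  Non-negative coefficients keep the background
#: non-negative; the peak background (~8 units) is 5-10x the tallest band.
DEFAULT_BASELINE_COEFFS = np.array([5.0, 1.0, 1.0, 0.5, 0.3, 0.2])

#: Per-point band-position spread (cm^-1): real bands shift point to point
#: with local composition; the amide I position especially reflects the
#: protein secondary-structure mix, so its class-mean positions (1660 vs
#: 1656) overlap between points rather than being a deterministic marker.
DEFAULT_CENTER_JITTER = 0.8
AMIDE_I_CENTER_JITTER = 1.2

#: Channel noise, as a fraction of the tallest band amplitude across all
#: profiles (detector noise is a property of the instrument, not of the
#: tissue class, so every profile shares the same sigma).
DEFAULT_NOISE_FRACTION = 0.01

_GLOBAL_MAX_AMP: list[float] = []  # lazy cache


def global_max_amplitude() -> float:
    """Tallest generator band amplitude over every class and component."""
    if not _GLOBAL_MAX_AMP:
        best = 0.0
        for comp, classes in _TABLES.items():
            for tc, table in classes.items():
                for key, (fwhm, par, conv, _) in table.items():
                    cal = CAL_FACTORS[(comp, key)]
                    iso, aniso, _phi = _split_cos2(par / cal, conv / cal)
                    best = max(best, (iso + max(aniso, 0.0)) * _AREA_TO_HEIGHT / fwhm)
        for amps in DOUBLET_AMPLITUDES.values():
            best = max(best, amps["hb0"], amps["hb90"], amps["hn0"], amps["hn90"])
        _GLOBAL_MAX_AMP.append(best)
    return _GLOBAL_MAX_AMP[0]


def _split_cos2(parallel: float, conventional: float) -> tuple[float, float, float]:
    """(a_iso, a_aniso, orientation_deg) reproducing the two area targets."""
    if parallel >= conventional:
        orientation = 0.0
        a_aniso = 2.0 * (parallel - conventional)
        a_iso = 2.0 * conventional - parallel
    else:
        orientation = 90.0
        a_iso = parallel
        a_aniso = 2.0 * (conventional - parallel)
    if a_iso < 0:
        raise ValueError(
            f"inconsistent area targets (parallel={parallel}, "
            f"conventional={conventional}): conventional must be >= parallel/2"
        )
    return a_iso, a_aniso, orientation


def default_profile(
    tissue_class: str,
    component: str,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    baseline_coeffs: np.ndarray | None = None,
) -> TissueProfile:
    """Build the calibrated default TissueProfile for one class/component."""
    table = _TABLES[component][tissue_class]
    bands = []
    max_amp = 0.0
    for key, (fwhm, par, conv, jitter) in table.items():
        center = AMIDE_I_CENTER[tissue_class] if (component == "protein" and key == 1660) else float(key)
        cal = CAL_FACTORS[(component, key)]
        iso_area, aniso_area, orientation = _split_cos2(par / cal, conv / cal)
        h = _AREA_TO_HEIGHT / fwhm
        band = BandProfile(
            center=center,
            fwhm=fwhm,
            a_iso=iso_area * h,
            a_aniso=aniso_area * h,
            orientation_deg=orientation,
            shape_mix=1.0,
            rel_jitter=jitter,
            center_jitter=(
                AMIDE_I_CENTER_JITTER
                if (component == "protein" and key == 1660)
                else DEFAULT_CENTER_JITTER
            ),
        )
        bands.append(band)
        max_amp = max(max_amp, band.a_iso + max(band.a_aniso, 0.0))
    if component == "protein":
        amps = DOUBLET_AMPLITUDES[tissue_class]
        for amp0, amp90, center, fwhm in (
            (amps["hb0"], amps["hb90"], AMIDE_III["broad_center"], AMIDE_III["broad_fwhm"]),
            (amps["hn0"], amps["hn90"], AMIDE_III["narrow_center"], AMIDE_III["narrow_fwhm"]),
        ):
            a_iso, a_aniso, orientation = _cos2_from_endpoints(amp0, amp90)
            band = BandProfile(
                center=center,
                fwhm=fwhm,
                a_iso=a_iso,
                a_aniso=a_aniso,
                orientation_deg=orientation,
                shape_mix=1.0,
                rel_jitter=AMIDE_III["rel_jitter"],
                center_jitter=DEFAULT_CENTER_JITTER,
            )
            bands.append(band)
            max_amp = max(max_amp, band.a_iso + max(band.a_aniso, 0.0))
        bands.sort(key=lambda b: b.center)
    if baseline_coeffs is None:
        baseline_coeffs = DEFAULT_BASELINE_COEFFS.copy()
    return TissueProfile(
        tissue_class=tissue_class,
        component=component,
        bands=bands,
        baseline_coeffs=np.asarray(baseline_coeffs, dtype=float),
        noise_sigma=noise_fraction * global_max_amplitude(),
    )


def default_profiles(**kwargs) -> dict[tuple[str, str], TissueProfile]:
    """All six default (tissue_class, component) profiles."""
    return {
        (tc, comp): default_profile(tc, comp, **kwargs)
        for comp in ("protein", "lipid")
        for tc in ("normal", "paracancerous", "cancerous")
    }


def default_grid() -> WavenumberGrid:
    return WavenumberGrid()
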