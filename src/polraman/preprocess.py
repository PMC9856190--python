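"""Spectral preprocessing: fluorescence removal, component classification,
reference-band normalization, and trough-baseline band integration.

Fluorescence removal uses iterative modified polynomial fitting: fit a
polynomial to the spectrum, replace every point lying above the fit by
the fit, and repeat until the working signal stops changing.  The final
polynomial is the background estimate.  This is the standard automated
scheme for biological Raman fluorescence baselines.

Band quantities use a local trough baseline: within a search window the
peak channel is located, the nearest flanking local minima (troughs) are
found on a lightly smoothed copy, and the straight line joining the two
troughs is subtracted before measuring peak height and the trapezoidal
band area (negative excursions clipped to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .profiles import REFERENCE_BAND
from .spectra import Cohort, PolarizationSeries, Spectrum, WavenumberGrid

__all__ = [
    "BaselineFitResult",
    "BandWindow",
    "BandMeasure",
    "remove_baseline",
    "remove_baseline_batch",
    "classify_component",
    "normalize_reference",
    "band_measure",
    "band_area",
    "peak_height",
    "preprocess_series",
    "preprocess_cohort",
]


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum cannot be normalized (reference band <= 0)."""


@dataclass
class BaselineFitResult:
    corrected: Spectrum
    baseline: np.ndarray
    n_iterations: int
    converged: bool


@dataclass(frozen=True)
class BandWindow:
    """Search window for a band: peak sought within center +/- halfwidth;
    troughs sought within center +/- 2*halfwidth."""

    center: float
    search_halfwidth: float = 20.0

    def __post_init__(self) -> None:
        if self.search_halfwidth <= 0:
            raise ValueError("search_halfwidth must be positive")


@dataclass
class BandMeasure:
    """Trough-baseline measurement of one band."""

    center: float
    area: float
    height: float
    ok: bool  # False when no interior maximum exists (monotone segment)
    trough_lo: int = -1
    trough_hi: int = -1
    peak_index: int = -1


# ---------------------------------------------------------------------------
# Fluorescence background removal
# ---------------------------------------------------------------------------

def _modpoly(
    y: np.ndarray, x: np.ndarray, poly_order: int, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized iterative modified polynomial fit.

    ``y`` is (n_spectra, n_channels); returns (baselines, n_iter, converged).
    Convergence: the max absolute change of the working signal, relative to
    the max absolute value of the input, falls below ``tol``.
    """
    # shared least-squares operator on the scaled domain for conditioning
    xs = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    vand = np.polynomial.polynomial.polyvander(xs, poly_order)
    solver = np.linalg.pinv(vand)  # (order+1, n_channels)

    work = y.copy()
    scale = np.maximum(np.abs(y).max(axis=1), np.finfo(float).tiny)
    n_iter = np.zeros(y.shape[0], dtype=int)
    converged = np.zeros(y.shape[0], dtype=bool)
    active = np.ones(y.shape[0], dtype=bool)
    baseline = np.zeros_like(y)

    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        coeffs = work[idx] @ solver.T
        fit = coeffs @ vand.T
        clipped = np.minimum(work[idx], fit)
        change = np.abs(clipped - work[idx]).max(axis=1) / scale[idx]
        baseline[idx] = fit
        work[idx] = clipped
        n_iter[idx] = it
        done = change < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    return baseline, n_iter, converged


def remove_baseline(
    spectrum: Spectrum,
    poly_order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> BaselineFitResult:
    """Remove the fluorescence background from one spectrum."""
    if poly_order < 1:
        raise ValueError("poly_order must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    y = spectrum.intensities[None, :]
    baseline, n_iter, converged = _modpoly(
        y, spectrum.grid.wavenumbers, poly_order, max_iter, tol
    )
    corrected = spectrum.with_intensities(spectrum.intensities - baseline[0])
    return BaselineFitResult(
        corrected=corrected,
        baseline=baseline[0],
        n_iterations=int(n_iter[0]),
        converged=bool(converged[0]),
    )


def remove_baseline_batch(
    intensities: np.ndarray,
    grid: WavenumberGrid,
    poly_order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized variant over a (n_spectra, n_channels) stack.

    Returns (corrected, n_iterations, converged); identical math to
    :func:`remove_baseline` row by row.
    """
    y = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("spectra must be finite")
    baseline, n_iter, converged = _modpoly(
        y, grid.wavenumbers, poly_order, max_iter, tol
    )
    return y - baseline, n_iter, converged


# ---------------------------------------------------------------------------
# Trough-baseline band machinery
# ---------------------------------------------------------------------------

def _smooth5(y: np.ndarray) -> np.ndarray:
    """5-channel moving average with edge replication (for trough search)."""
    pad = np.pad(y, 2, mode="edge")
    kernel = np.ones(5) / 5.0
    return np.convolve(pad, kernel, mode="valid")


def _walk_to_trough(
    ys: np.ndarray, peak: int, bound: int, step: int, noise: float
) -> int:
    """Walk outward from ``peak`` to the nearest flanking trough.

    The trough is the running minimum of the (smoothed) signal; the walk
    stops once the signal rises significantly above it — more than 5% of
    the descent so far plus a noise-scale allowance — so that shallow
    noise minima on a band flank are not mistaken for the trough.
    """
    best = peak
    best_val = ys[peak]
    i = peak
    while i != bound:
        i += step
        v = ys[i]
        if v < best_val:
            best, best_val = i, v
        elif v - best_val > 0.05 * (ys[peak] - best_val) + 2.0 * noise:
            break
    return best


def band_measure(
    spectrum: Spectrum, window: BandWindow, smooth_troughs: bool = True
) -> BandMeasure:
    """Locate the band in ``window`` and measure its trough-baseline
    area and height.

    The peak is the maximum channel within center +/- halfwidth; troughs
    are the nearest flanking local minima of a lightly smoothed copy,
    bounded by center +/- 2*halfwidth.  A straight line through the raw
    trough values is subtracted; the positive part is integrated by the
    trapezoid rule (x in cm^-1).
    """
    grid = spectrum.grid
    if not (grid.start <= window.center - window.search_halfwidth) or not (
        window.center + window.search_halfwidth <= grid.stop
    ):
        raise ValueError(
            f"band window {window.center}±{window.search_halfwidth} cm^-1 "
            "outside the wavenumber grid"
        )
    y = spectrum.intensities
    w = grid.wavenumbers
    lo = grid.index_of(max(window.center - window.search_halfwidth, grid.start))
    hi = grid.index_of(min(window.center + window.search_halfwidth, grid.stop))
    blo = grid.index_of(max(window.center - 2 * window.search_halfwidth, grid.start))
    bhi = grid.index_of(min(window.center + 2 * window.search_halfwidth, grid.stop))

    ys = _smooth5(y) if smooth_troughs else y
    peak = lo + int(np.argmax(y[lo : hi + 1]))
    # a maximum pinned to the search-window edge with a rising neighbour
    # outside is the flank of a different band, not this band's maximum;
    # fall back to the strongest interior local maximum of the smoothed
    # signal, and flag a monotone segment when none exists
    if (peak == lo and peak > blo and y[peak - 1] >= y[peak]) or (
        peak == hi and peak < bhi and y[peak + 1] >= y[peak]
    ):
        seg = ys[lo : hi + 1]
        interior = [
            i
            for i in range(1, len(seg) - 1)
            if seg[i] >= seg[i - 1] and seg[i] >= seg[i + 1]
        ]
        if not interior:
            return BandMeasure(window.center, 0.0, 0.0, ok=False)
        peak = lo + max(interior, key=lambda i: seg[i])
    # noise floor from raw second differences (robust), for the rise
    # tolerance that keeps the walk from stopping at noise minima
    d2 = np.diff(y[blo : bhi + 1], n=2)
    noise = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)
    t_lo = _walk_to_trough(ys, peak, blo, -1, noise)
    t_hi = _walk_to_trough(ys, peak, bhi, +1, noise)
    if t_lo == peak and t_hi == peak:
        return BandMeasure(window.center, 0.0, 0.0, ok=False)

    # straight baseline through robust trough values: the raw (or even
    # smoothed) value at the selected index is a running minimum of noise
    # and therefore biased low, which would inflate small band areas; a
    # local median around the trough index is unbiased at the noise floor.
    # Integration itself uses raw intensities.
    def _trough_value(idx: int) -> float:
        a = max(idx - 3, 0)
        b = min(idx + 4, len(y))
        return float(np.median(y[a:b]))

    xx = w[t_lo : t_hi + 1]
    line = np.interp(xx, [w[t_lo], w[t_hi]], [_trough_value(t_lo), _trough_value(t_hi)])
    signal = np.clip(y[t_lo : t_hi + 1] - line, 0.0, None)
    area = float(np.trapezoid(signal, xx))
    height = float(signal.max())
    return BandMeasure(
        window.center, area, height, ok=True,
        trough_lo=t_lo, trough_hi=t_hi, peak_index=peak,
    )


def band_area(spectrum: Spectrum, window: BandWindow) -> float:
    """Trough-baseline band area (cm^-1 x intensity units)."""
    return band_measure(spectrum, window).area


def peak_height(spectrum: Spectrum, window: BandWindow) -> float:
    """Trough-baseline-subtracted peak height (>= 0)."""
    return band_measure(spectrum, window).height


# ---------------------------------------------------------------------------
# Component classification and normalization
# ---------------------------------------------------------------------------

def classify_component(spectrum: Spectrum, halfwidth: float = 15.0) -> str:
    """Protein vs lipid call on a baseline-corrected spectrum.

    Protein spectra alone carry the phenylalanine 1003 cm^-1 and amide III
    1247 cm^-1 bands; lipid spectra alone carry 1084 and 1745 cm^-1.
    """
    def h(center: float) -> float:
        return band_measure(spectrum, BandWindow(center, halfwidth)).height

    protein_score = h(1003.0) + h(1247.0)
    lipid_score = h(1084.0) + h(1745.0)
    return "protein" if protein_score > lipid_score else "lipid"


def normalize_reference(
    spectrum: Spectrum, component: str, halfwidth: float = 8.0
) -> Spectrum:
    """Divide by the maximum intensity within +/-8 cm^-1 of the reference
    band (1450 cm^-1 for protein, 1442 cm^-1 for lipid)."""
    center = REFERENCE_BAND[component]
    grid = spectrum.grid
    lo = grid.index_of(center - halfwidth)
    hi = grid.index_of(center + halfwidth)
    ref = float(spectrum.intensities[lo : hi + 1].max())
    if ref <= 0:
        raise DegenerateSpectrumError(
            f"reference band at {center} cm^-1 has non-positive maximum ({ref})"
        )
    return spectrum.with_intensities(spectrum.intensities / ref)


# ---------------------------------------------------------------------------
# Pipeline drivers
# ---------------------------------------------------------------------------

def preprocess_series(
    series: PolarizationSeries,
    poly_order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> PolarizationSeries:
    """Baseline-correct and normalize all 13 spectra of a detection point.

    The protein/lipid component is classified once, on the corrected
    conventional spectrum, and applied to the whole point (the 13 spectra
    probe the same tissue volume); the call is stored in
    ``series.component_label``.
    """
    stack = np.vstack([series.stack(), series.conventional.intensities[None, :]])
    corrected, _, _ = remove_baseline_batch(
        stack, series.conventional.grid, poly_order, max_iter, tol
    )
    conv = series.conventional.with_intensities(corrected[-1])
    component = classify_component(conv)
    new_spectra = [
        normalize_reference(s.with_intensities(c), component)
        for s, c in zip(series.spectra, corrected[:-1])
    ]
    new_conv = normalize_reference(conv, component)
    return PolarizationSeries(
        spectra=new_spectra, conventional=new_conv, component_label=component
    )


def preprocess_cohort(cohort: Cohort, **kwargs) -> Cohort:
    """Apply :func:`preprocess_series` to every detection point."""
    return Cohort(
        series=[preprocess_series(s, **kwargs) for s in cohort.series],
        grid=cohort.grid,
        seed=cohort.seed,
    )
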