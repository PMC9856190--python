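"""Band-area tables, Welch t-tests, and anisotropy ratio analyses.

Reproduces the study-style statistics on a preprocessed cohort:

* per-class mean +/- std trough-baseline band areas, for parallel
  polarized (0°) and conventional spectra;
* independent-sample (Welch) t-tests of band areas between classes;
* the amide III bimodal ratio I1247/I1269 as a function of polarization
  angle (the collagen-orientation signature: < 1 at 0° and > 1 at 90° in
  normal tissue, never above 1 in cancerous tissue);
* the hydroxyproline/proline area ratio I875/I921 and the lipid
  unsaturation height ratio I1652/I1442.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BandWindow, band_area, band_measure, peak_height
from .profiles import LIPID_BAND_CENTERS, PROTEIN_BAND_CENTERS, band_window_halfwidth
from .spectra import ANGLES_DEG, Cohort, PolarizationSeries, Spectrum

__all__ = [
    "RatioCurve",
    "band_area_table",
    "collect_band_areas",
    "ttest_band",
    "bimodal_ratio_curve",
    "mean_ratio_curves",
    "hydroxyproline_ratio",
    "unsaturation_ratio",
]

#: Band-position keys per component (amide I measured at the class position
#: via a window around the normal-tissue 1660 cm^-1 center, which also
#: contains the cancerous 1656 cm^-1 position).
BAND_LISTS = {"protein": PROTEIN_BAND_CENTERS, "lipid": LIPID_BAND_CENTERS}


@dataclass
class RatioCurve:
    """I1247/I1269 peak-height ratio at each of the 12 polarization angles."""

    angles: np.ndarray
    ratio: np.ndarray
    tissue_class: str = ""
    valid: np.ndarray = field(default_factory=lambda: np.ones(12, dtype=bool))


def _mode_spectrum(series: PolarizationSeries, mode: str) -> Spectrum:
    if mode == "polarized":
        return series.at_angle(0.0)
    if mode == "conventional":
        return series.conventional
    raise ValueError(f"mode must be 'polarized' or 'conventional', got {mode!r}")


def collect_band_areas(
    cohort: Cohort,
    component: str,
    band_centers=None,
    mode: str = "polarized",
    search_halfwidth: float = 20.0,
) -> pd.DataFrame:
    """Long table of per-spectrum band areas: one row per (series, band).

    Series are selected by their preprocessing-assigned component label.
    """
    if band_centers is None:
        band_centers = BAND_LISTS[component]
    rows = []
    for ser in cohort.series:
        if ser.component_label != component:
            continue
        spec = _mode_spectrum(ser, mode)
        for center in band_centers:
            hw = band_window_halfwidth(component, center, search_halfwidth)
            m = band_measure(spec, BandWindow(float(center), hw))
            rows.append(
                {
                    "band_center": center,
                    "tissue_class": ser.tissue_class,
                    "mode": mode,
                    "patient_id": ser.patient_id,
                    "sample_id": ser.sample_id,
                    "point_index": ser.point_index,
                    "area": m.area,
                    "height": m.height,
                    "ok": m.ok,
                }
            )
    return pd.DataFrame(rows)


def band_area_table(
    cohort: Cohort,
    component: str,
    band_centers=None,
    mode: str = "polarized",
) -> pd.DataFrame:
    """Per-class mean +/- std of trough-baseline band areas.

    Rows are keyed by (band_center, tissue_class, mode).  Class/band
    combinations without any qualifying spectrum are flagged missing
    (NaN mean, n = 0) rather than fabricated.
    """
    long = collect_band_areas(cohort, component, band_centers, mode)
    if band_centers is None:
        band_centers = BAND_LISTS[component]
    classes = sorted({s.tissue_class for s in cohort.series})
    rows = []
    for center in band_centers:
        for tc in classes:
            sel = long[(long.band_center == center) & (long.tissue_class == tc)]
            if len(sel) == 0:
                rows.append(
                    {
                        "band_center": center,
                        "tissue_class": tc,
                        "mode": mode,
                        "mean_area": np.nan,
                        "std_area": np.nan,
                        "n": 0,
                        "missing": True,
                    }
                )
            else:
                rows.append(
                    {
                        "band_center": center,
                        "tissue_class": tc,
                        "mode": mode,
                        "mean_area": float(sel.area.mean()),
                        "std_area": float(sel.area.std(ddof=0)),
                        "n": int(len(sel)),
                        "missing": False,
                    }
                )
    return pd.DataFrame(rows)


def ttest_band(areas_a: np.ndarray, areas_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test on two area samples.

    Degenerate case: both groups with zero variance and equal means gives
    (0.0, 1.0) by convention.
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("band areas must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def significance_table(
    cohort: Cohort, component: str, classes=("normal", "cancerous")
) -> pd.DataFrame:
    """Per-band Welch p-values between two classes, for parallel-polarized
    and conventional spectra (pooled per-spectrum areas)."""
    rows = []
    for mode in ("polarized", "conventional"):
        long = collect_band_areas(cohort, component, mode=mode)
        for center in BAND_LISTS[component]:
            a = long[(long.band_center == center) & (long.tissue_class == classes[0])].area
            b = long[(long.band_center == center) & (long.tissue_class == classes[1])].area
            t, p = ttest_band(a.to_numpy(), b.to_numpy())
            rows.append(
                {"band_center": center, "mode": mode, "t": t, "p": p}
            )
    return pd.DataFrame(rows)


def bimodal_ratio_curve(
    series: PolarizationSeries, search_halfwidth: float = 12.0
) -> RatioCurve:
    """Amide III bimodal ratio I1247/I1269 across the 12 angles.

    Peak intensities are trough-baseline-subtracted heights.  Angles with
    a zero denominator are flagged invalid (NaN ratio), not fabricated.
    """
    ratios = np.empty(12)
    valid = np.ones(12, dtype=bool)
    for i, theta in enumerate(ANGLES_DEG):
        spec = series.at_angle(theta)
        num = peak_height(spec, BandWindow(1247.0, search_halfwidth))
        den = peak_height(spec, BandWindow(1269.0, search_halfwidth))
        if den <= 0:
            ratios[i] = np.nan
            valid[i] = False
        else:
            ratios[i] = num / den
    return RatioCurve(
        angles=ANGLES_DEG.copy(),
        ratio=ratios,
        tissue_class=series.tissue_class,
        valid=valid,
    )


def mean_ratio_curves(cohort: Cohort, search_halfwidth: float = 12.0) -> pd.DataFrame:
    """Class bimodal-ratio curves over all protein-labelled points.

    Two statistics per (tissue_class, angle): ``mean_ratio``/``std_ratio``
    over the per-point ratios, and ``pooled_ratio`` — the ratio of the
    class-mean peak heights, the average-spectrum statistic (robust: a
    single noisy near-zero denominator cannot dominate it).
    """
    rows = []
    for ser in cohort.series:
        if ser.component_label != "protein":
            continue
        for theta in ANGLES_DEG:
            spec = ser.at_angle(theta)
            num = peak_height(spec, BandWindow(1247.0, search_halfwidth))
            den = peak_height(spec, BandWindow(1269.0, search_halfwidth))
            rows.append(
                {
                    "tissue_class": ser.tissue_class,
                    "angle_deg": theta,
                    "h1247": num,
                    "h1269": den,
                    "ratio": num / den if den > 0 else np.nan,
                }
            )
    long = pd.DataFrame(rows)
    g = long.groupby(["tissue_class", "angle_deg"])
    out = g.agg(
        mean_ratio=("ratio", "mean"),
        std_ratio=("ratio", "std"),
        mean_h1247=("h1247", "mean"),
        mean_h1269=("h1269", "mean"),
        n=("ratio", "count"),
    ).reset_index()
    out["pooled_ratio"] = out.mean_h1247 / out.mean_h1269
    return out


def hydroxyproline_table(cohort: Cohort) -> pd.DataFrame:
    """Hydroxyproline/proline area ratio I875/I921 per class and mode.

    The cohort-level statistic is the ratio of class-mean areas (the
    analog of measuring the ratio in the class-average spectrum).
    """
    rows = []
    for mode in ("conventional", "polarized"):
        long = collect_band_areas(cohort, "protein", band_centers=(875, 921), mode=mode)
        for tc, sub in long.groupby("tissue_class"):
            a875 = sub[sub.band_center == 875].area.mean()
            a921 = sub[sub.band_center == 921].area.mean()
            rows.append(
                {
                    "tissue_class": tc,
                    "mode": mode,
                    "ratio": a875 / a921 if a921 > 0 else np.nan,
                    "n": int((sub.band_center == 875).sum()),
                }
            )
    return pd.DataFrame(rows)


def hydroxyproline_ratio(spectrum: Spectrum, search_halfwidth: float = 15.0) -> float:
    """Integral-area ratio I875/I921 (hydroxyproline over proline)."""
    num = band_area(spectrum, BandWindow(875.0, search_halfwidth))
    den = band_area(spectrum, BandWindow(921.0, search_halfwidth))
    if den <= 0:
        return np.nan
    return num / den


def unsaturation_ratio(spectrum: Spectrum, search_halfwidth: float = 20.0) -> float:
    """Lipid unsaturation height ratio I1652/I1442 (C=C over CH2)."""
    num = peak_height(spectrum, BandWindow(1652.0, search_halfwidth))
    den = peak_height(spectrum, BandWindow(1442.0, search_halfwidth))
    if den <= 0:
        return np.nan
    return num / den
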