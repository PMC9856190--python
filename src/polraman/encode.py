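"""Encode a detection point's 12-angle polarization stack as a pseudo-color
image suitable for a 2D-CNN.

The 12 preprocessed spectra are stacked into a 12 x n_channels matrix
(rows ascending by angle), density-sliced into discrete levels between
per-matrix percentile clips, mapped through a fixed 256-entry jet-style
RGB lookup table, and resized to 100 x 100 by exact area interpolation.
All steps are deterministic; PNG export applies the single 8-bit
quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .spectra import ANGLES_DEG, Cohort, PolarizationSeries

__all__ = [
    "PolarizationMatrix",
    "EncodedImage",
    "assemble_matrix",
    "density_slice",
    "to_pseudocolor",
    "encode_series",
    "encode_cohort",
    "save_png",
    "load_png",
]

#: Class labels for the discrimination task.
LABELS = {"cancerous": 0, "normal": 1}

IMAGE_SIZE = 100

#: Fixed 256-entry RGB lookup table (jet-style), values in [0, 1].
JET_LUT: np.ndarray = np.asarray(
    colormaps["jet"](np.linspace(0.0, 1.0, 256))[:, :3], dtype=np.float64
)


@dataclass
class PolarizationMatrix:
    values: np.ndarray  # (12, n_channels), rows ascending by angle
    patient_id: str = ""
    sample_id: str = ""
    tissue_class: str = ""
    point_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 12:
            raise ValueError(f"expected a 12-row matrix, got {self.values.shape}")


@dataclass
class EncodedImage:
    pixels: np.ndarray  # (100, 100, 3) in [0, 1]
    label: int
    patient_id: str = ""
    sample_id: str = ""
    tissue_class: str = ""
    point_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"expected (100, 100, 3) pixels, got {self.pixels.shape}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (cancerous) or 1 (normal)")


def assemble_matrix(series: PolarizationSeries) -> PolarizationMatrix:
    """Stack the 12 polarized spectra, sorted by ascending angle."""
    for theta in ANGLES_DEG:
        try:
            series.at_angle(theta)
        except KeyError as exc:
            raise ValueError(f"series is missing the {theta}° spectrum") from exc
    return PolarizationMatrix(
        values=series.stack(),
        patient_id=series.patient_id,
        sample_id=series.sample_id,
        tissue_class=series.tissue_class,
        point_index=series.point_index,
    )


def density_slice(
    matrix: np.ndarray | PolarizationMatrix,
    n_levels: int = 64,
    clip_lo_pct: float = 1.0,
    clip_hi_pct: float = 99.0,
) -> np.ndarray:
    """Clip to per-matrix percentiles and quantize to 0..n_levels-1."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    values = matrix.values if isinstance(matrix, PolarizationMatrix) else np.asarray(matrix)
    lo, hi = np.percentile(values, [clip_lo_pct, clip_hi_pct])
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    scaled = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    return np.rint(scaled * (n_levels - 1)).astype(np.int64)


def _overlap_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Exact area-interpolation operator (n_out, n_in): output cell i
    averages input cells weighted by interval overlap."""
    edges_out = np.linspace(0.0, n_in, n_out + 1)
    op = np.zeros((n_out, n_in))
    for i in range(n_out):
        a, b = edges_out[i], edges_out[i + 1]
        j0, j1 = int(np.floor(a)), int(np.ceil(b))
        for j in range(j0, min(j1, n_in)):
            op[i, j] = max(0.0, min(b, j + 1) - max(a, j))
        op[i] /= b - a
    return op


def _area_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """(H, W, C) -> (out_h, out_w, C) by exact area interpolation."""
    rows = _overlap_matrix(img.shape[0], out_h)
    cols = _overlap_matrix(img.shape[1], out_w)
    return np.einsum("ih,hwc,jw->ijc", rows, img, cols, optimize=True)


def to_pseudocolor(
    levels: np.ndarray,
    n_levels: int = 64,
    size: int = IMAGE_SIZE,
) -> np.ndarray:
    """Map integer levels through the jet LUT and area-resize to
    (size, size, 3) float pixels in [0, 1]."""
    levels = np.asarray(levels)
    lut_idx = np.rint(levels * (255.0 / (n_levels - 1))).astype(np.int64)
    if lut_idx.min() < 0 or lut_idx.max() > 255:
        raise ValueError("levels out of range for the 256-entry LUT")
    rgb = JET_LUT[lut_idx]
    out = _area_resize(rgb, size, size)
    return np.clip(out, 0.0, 1.0)


def encode_series(
    series: PolarizationSeries,
    n_levels: int = 64,
    clip_lo_pct: float = 1.0,
    clip_hi_pct: float = 99.0,
) -> EncodedImage:
    """Full encoding of one (preprocessed) detection point."""
    if series.tissue_class not in LABELS:
        raise ValueError(
            f"no discrimination label for tissue class {series.tissue_class!r}"
        )
    matrix = assemble_matrix(series)
    levels = density_slice(matrix, n_levels, clip_lo_pct, clip_hi_pct)
    pixels = to_pseudocolor(levels, n_levels)
    return EncodedImage(
        pixels=pixels.astype(np.float32),
        label=LABELS[series.tissue_class],
        patient_id=series.patient_id,
        sample_id=series.sample_id,
        tissue_class=series.tissue_class,
        point_index=series.point_index,
        metadata={
            "n_levels": n_levels,
            "clip_lo_pct": clip_lo_pct,
            "clip_hi_pct": clip_hi_pct,
            "colormap": "jet",
            "resize": "area",
        },
    )


def encode_cohort(cohort: Cohort, **kwargs) -> list[EncodedImage]:
    """Encode every cancerous/normal detection point of a preprocessed
    cohort (paracancerous points carry no discrimination label)."""
    return [
        encode_series(s, **kwargs)
        for s in cohort.series
        if s.tissue_class in LABELS
    ]


def save_png(image: EncodedImage, path: str | Path) -> Path:
    """Write 8-bit RGB PNG; the one quantization step of the pipeline."""
    path = Path(path)
    arr = np.rint(np.asarray(image.pixels, dtype=float) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")
    return path


def load_png(path: str | Path) -> np.ndarray:
    """Read a PNG back to float pixels in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr / 255.0
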