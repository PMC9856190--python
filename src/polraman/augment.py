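"""Training-set expansion and train/validation splitting.

Three augmentation families act on encoded images: horizontal/vertical
flips, 90°/180°/270° rotations, and additive Gaussian noise with nonzero
means 0.1/0.2/0.3 (pixels clipped back to [0, 1]).  ``expand_to_n``
balances both classes to an exact per-class count, keeping every
original and cycling seeded augmentations for the remainder, with full
provenance.  Expansion happens per cross-validation fold, strictly after
the train/test split, so test points never seed an augmentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "flip",
    "rotate",
    "add_noise",
    "AUGMENTATION_OPS",
    "expand_to_n",
    "expand_spectra_to_n",
    "split_train_val",
]


def flip(image: np.ndarray, axis: str) -> np.ndarray:
    """Flip horizontally (axis='h', mirrors columns) or vertically ('v')."""
    if axis == "h":
        return image[:, ::-1].copy()
    if axis == "v":
        return image[::-1].copy()
    raise ValueError("axis must be 'h' or 'v'")


def rotate(image: np.ndarray, k: int) -> np.ndarray:
    """Rotate a square image by k*90 degrees counterclockwise."""
    if image.shape[0] != image.shape[1]:
        raise ValueError("rotation requires a square image")
    return np.rot90(image, k=k % 4, axes=(0, 1)).copy()


def add_noise(
    image: np.ndarray,
    mean: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pixel-wise Gaussian noise with nonzero mean, clipped to [0, 1]."""
    noisy = image + rng.normal(mean, sigma, size=image.shape)
    return np.clip(noisy, 0.0, 1.0)


#: The eight augmentation operations: 2 flips, 3 rotations, 3 noise levels.
AUGMENTATION_OPS: dict[str, callable] = {
    "flip_h": lambda img, rng, sigma: flip(img, "h"),
    "flip_v": lambda img, rng, sigma: flip(img, "v"),
    "rot90": lambda img, rng, sigma: rotate(img, 1),
    "rot180": lambda img, rng, sigma: rotate(img, 2),
    "rot270": lambda img, rng, sigma: rotate(img, 3),
    "noise_0.1": lambda img, rng, sigma: add_noise(img, 0.1, sigma, rng),
    "noise_0.2": lambda img, rng, sigma: add_noise(img, 0.2, sigma, rng),
    "noise_0.3": lambda img, rng, sigma: add_noise(img, 0.3, sigma, rng),
}


def _expand_class(
    images: np.ndarray,
    n_target: int,
    rng: np.random.Generator,
    op_names: list[str],
    ops: dict,
    noise_sigma: float,
) -> tuple[list[np.ndarray], list[dict]]:
    n_orig = len(images)
    out = [images[i] for i in range(n_orig)]
    manifest = [{"source": i, "op": "original"} for i in range(n_orig)]
    for j in range(n_target - n_orig):
        src = j % n_orig
        op = op_names[int(rng.integers(len(op_names)))]
        out.append(ops[op](images[src], rng, noise_sigma))
        manifest.append({"source": src, "op": op})
    return out, manifest


def expand_to_n(
    images: np.ndarray,
    labels: np.ndarray,
    n_per_class: int = 5000,
    seed: int = 0,
    noise_sigma: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Balance both classes to exactly ``n_per_class`` images.

    All originals are retained; the remainder cycles through the class
    originals, applying one of the eight augmentations drawn uniformly
    (seeded).  Returns (images, labels, manifest); the manifest records
    the source index (into the input array) and operation of every image.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    op_names = sorted(AUGMENTATION_OPS)
    all_imgs: list[np.ndarray] = []
    all_rows: list[dict] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls} has no images to augment")
        if idx.size > n_per_class:
            raise ValueError(
                f"class {cls} already has {idx.size} > n_per_class={n_per_class} images"
            )
        cls_imgs, manifest = _expand_class(
            images[idx], n_per_class, rng, op_names, AUGMENTATION_OPS, noise_sigma
        )
        for row in manifest:
            row["label"] = cls
            row["source"] = int(idx[row["source"]])
        all_imgs.extend(cls_imgs)
        all_rows.extend(manifest)
    out_labels = np.array([r["label"] for r in all_rows], dtype=np.int64)
    return (
        np.stack(all_imgs).astype(np.float32),
        out_labels,
        pd.DataFrame(all_rows),
    )


#: Spectrum "augmentations": the flip/rotation families are image
#: operations with no physical meaning for a 1-D spectrum, so the
#: conventional-spectrum branch balances classes with the noise-injection
#: family alone (means 0.1/0.2/0.3, intensities clipped at zero only).
SPECTRUM_OPS: dict[str, callable] = {
    "noise_0.1": lambda s, rng, sigma: np.clip(s + rng.normal(0.1, sigma, s.shape), 0.0, None),
    "noise_0.2": lambda s, rng, sigma: np.clip(s + rng.normal(0.2, sigma, s.shape), 0.0, None),
    "noise_0.3": lambda s, rng, sigma: np.clip(s + rng.normal(0.3, sigma, s.shape), 0.0, None),
}


def expand_spectra_to_n(
    spectra: np.ndarray,
    labels: np.ndarray,
    n_per_class: int = 5000,
    seed: int = 0,
    noise_sigma: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Class balancing for 1-D conventional spectra (noise ops only)."""
    spectra = np.asarray(spectra)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    op_names = sorted(SPECTRUM_OPS)
    all_specs: list[np.ndarray] = []
    all_rows: list[dict] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls} has no spectra to augment")
        cls_specs, manifest = _expand_class(
            spectra[idx], n_per_class, rng, op_names, SPECTRUM_OPS, noise_sigma
        )
        for row in manifest:
            row["label"] = cls
            row["source"] = int(idx[row["source"]])
        all_specs.extend(cls_specs)
        all_rows.extend(manifest)
    out_labels = np.array([r["label"] for r in all_rows], dtype=np.int64)
    return (
        np.stack(all_specs).astype(np.float32),
        out_labels,
        pd.DataFrame(all_rows),
    )


def split_train_val(
    images: np.ndarray,
    labels: np.ndarray,
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split; returns (train_idx, val_idx).

    The two index arrays are disjoint and their union covers the input.
    """
    idx = np.arange(len(labels))
    train_idx, val_idx = train_test_split(
        idx,
        train_size=ratio,
        stratify=np.asarray(labels),
        random_state=seed,
        shuffle=True,
    )
    return np.sort(train_idx), np.sort(val_idx)
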