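"""Pipeline configuration: serializable dataclasses with YAML round-trip
and the named execution profiles.

Profiles
--------
full   The study-scale configuration: 20/10/12 samples, 10-fold
       cross-validation, 5000 images per class after augmentation,
       learning rate 5e-5 with thousands of iterations.
fast   Desk-scale: the same cohort but 2 of the 10 folds, 500 images per
       class and a few hundred iterations at a proportionally larger
       learning rate.  Used for CI and the acceptance run.
micro  A smoke-test cohort (4 cancerous / 2 normal samples, 2 folds)
       that exercises every stage in seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "profile_config"]


@dataclass
class GridSection:
    start: float = 500.0
    stop: float = 2000.0
    n_channels: int = 1780


@dataclass
class CohortSection:
    n_cancerous: int = 20
    n_normal: int = 10
    n_paracancerous: int = 12
    points_per_sample: int = 10
    protein_fraction: float = 0.5
    baseline_scale_sigma: float = 0.2


@dataclass
class PreprocessSection:
    poly_order: int = 5
    max_iter: int = 100
    tol: float = 1e-3


@dataclass
class EncodeSection:
    n_levels: int = 64
    clip_lo_pct: float = 1.0
    clip_hi_pct: float = 99.0


@dataclass
class AugmentSection:
    n_per_class: int = 5000
    noise_sigma: float = 0.05
    train_ratio: float = 0.7


@dataclass
class ModelSection:
    conv_channels: tuple[int, int] = (16, 32)
    kernel_size: int = 3
    fc_width: int = 128
    dropout: float = 0.5
    leaky_slope: float = 0.01
    lr: float = 5e-5
    lr_min: float | None = None  # cosine decay floor; None = constant rate
    batch_size: int = 64
    max_iters: int = 6000
    eval_every: int = 100
    patience: int = 10
    min_delta: float = 1e-4


@dataclass
class ExperimentSection:
    n_folds: int = 10
    folds_to_run: int | None = None  # None = all folds
    knn_k_values: tuple[int, ...] = (1, 3, 5, 7, 9)
    run_cnn1d: bool = True
    run_knn: bool = True


@dataclass
class PipelineConfig:
    profile: str = "full"
    seed: int = 0
    grid: GridSection = field(default_factory=GridSection)
    cohort: CohortSection = field(default_factory=CohortSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    encode: EncodeSection = field(default_factory=EncodeSection)
    augment: AugmentSection = field(default_factory=AugmentSection)
    cnn2d: ModelSection = field(default_factory=ModelSection)
    cnn1d: ModelSection = field(
        default_factory=lambda: ModelSection(kernel_size=7)
    )
    experiment: ExperimentSection = field(default_factory=ExperimentSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
                kwargs[f.name] = f.type(**value)
            elif f.name in _SECTION_TYPES and isinstance(value, dict):
                kwargs[f.name] = _SECTION_TYPES[f.name](**value)
            else:
                kwargs[f.name] = value
        cfg = cls(**kwargs)
        for name in ("cnn2d", "cnn1d"):
            section = getattr(cfg, name)
            if isinstance(section.conv_channels, list):
                section.conv_channels = tuple(section.conv_channels)
        if isinstance(cfg.experiment.knn_k_values, list):
            cfg.experiment.knn_k_values = tuple(cfg.experiment.knn_k_values)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))
        return path

    def hash(self) -> str:
        blob = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "grid": GridSection,
    "cohort": CohortSection,
    "preprocess": PreprocessSection,
    "encode": EncodeSection,
    "augment": AugmentSection,
    "cnn2d": ModelSection,
    "cnn1d": ModelSection,
    "experiment": ExperimentSection,
}


def _plain(obj):
    """Make a config dict YAML/JSON-safe (tuples -> lists)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def profile_config(profile: str = "full", seed: int = 0) -> PipelineConfig:
    """Build one of the named profiles."""
    if profile == "full":
        cfg = PipelineConfig(profile="full", seed=seed)
    elif profile == "fast":
        cfg = PipelineConfig(
            profile="fast",
            seed=seed,
            augment=AugmentSection(n_per_class=500),
            cnn2d=ModelSection(
                lr=2e-3, lr_min=1e-4, batch_size=32, max_iters=200,
                eval_every=50, patience=4, dropout=0.0,
            ),
            cnn1d=ModelSection(
                kernel_size=7, lr=2e-3, lr_min=1e-4, batch_size=64,
                max_iters=150, eval_every=50, patience=4, dropout=0.0,
            ),
            experiment=ExperimentSection(folds_to_run=2, knn_k_values=(1, 3, 5)),
        )
    elif profile == "micro":
        cfg = PipelineConfig(
            profile="micro",
            seed=seed,
            cohort=CohortSection(
                n_cancerous=4, n_normal=2, n_paracancerous=0, points_per_sample=4
            ),
            augment=AugmentSection(n_per_class=24),
            cnn2d=ModelSection(
                lr=3e-3, batch_size=16, max_iters=40, eval_every=10, patience=3
            ),
            cnn1d=ModelSection(
                kernel_size=7, lr=3e-3, batch_size=16, max_iters=40,
                eval_every=10, patience=3,
            ),
            experiment=ExperimentSection(n_folds=2, knn_k_values=(1, 3)),
        )
    else:
        raise ValueError(f"unknown profile {profile!r} (full/fast/micro)")
    return cfg
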