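"""Patient-grouped cross-validation and the model comparison report.

The discrimination experiment uses only the two labelled classes
(cancerous = 0, normal = 1); paracancerous points are excluded.  Fold
groups follow the 2-cancerous + 1-normal pattern with every patient's
samples confined to a single group: a patient who contributed both a
normal and a cancerous sample has them grouped together, so no patient
ever spans a train/test split.

Per fold, confusion matrices are row-normalized ("predictive ratios");
aggregation takes the cell-wise mean across folds with the per-cell mean
squared deviation (MSE), and the overall accuracy is the mean of the two
diagonal means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import expand_spectra_to_n, expand_to_n, split_train_val
from .config import PipelineConfig, profile_config
from .encode import LABELS, encode_cohort
from .models import CNN1DClassifier, CNN2DClassifier, KNNImageClassifier
from .preprocess import preprocess_cohort
from .spectra import Cohort, WavenumberGrid
from .synth import CohortConfig, synth_cohort

__all__ = [
    "FoldPlan",
    "grouped_kfold",
    "confusion_ratio",
    "aggregate_confusion",
    "run_experiment",
]


@dataclass
class FoldPlan:
    """k disjoint groups of sample ids (2 cancerous + 1 normal each)."""

    groups: list[list[str]]
    sample_class: dict[str, str] = field(default_factory=dict)
    sample_patient: dict[str, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.groups)

    def validate(self) -> None:
        seen: set[str] = set()
        for group in self.groups:
            classes = sorted(self.sample_class[s] for s in group)
            if classes != ["cancerous", "cancerous", "normal"]:
                raise ValueError(f"group {group} violates the 2+1 class pattern")
            if seen & set(group):
                raise ValueError("fold groups are not disjoint")
            seen |= set(group)
        if seen != set(self.sample_class):
            raise ValueError("fold groups do not cover all classification samples")
        patient_group: dict[str, int] = {}
        for gi, group in enumerate(self.groups):
            for s in group:
                p = self.sample_patient[s]
                if patient_group.setdefault(p, gi) != gi:
                    raise ValueError(f"patient {p} spans two fold groups")


def grouped_kfold(samples: pd.DataFrame | list[dict], k: int = 10, seed: int = 0) -> FoldPlan:
    """Deterministic patient-grouped fold assignment.

    ``samples`` needs columns sample_id / patient_id / tissue_class;
    classes other than cancerous/normal are ignored.  Requires exactly
    2k cancerous and k normal samples.
    """
    df = pd.DataFrame(samples)
    df = df[df.tissue_class.isin(LABELS)].reset_index(drop=True)
    cancerous = df[df.tissue_class == "cancerous"]
    normal = df[df.tissue_class == "normal"]
    if len(cancerous) != 2 * k or len(normal) != k:
        raise ValueError(
            f"patient-grouped {k}-fold CV needs exactly {2 * k} cancerous and "
            f"{k} normal samples (2+1 per group); got "
            f"{len(cancerous)} cancerous, {len(normal)} normal"
        )
    rng = np.random.default_rng(seed)

    # anchor each group on one normal sample plus its patient's cancerous
    # sample (when present), then fill with unclaimed cancerous samples
    groups: list[list[str]] = []
    claimed: set[str] = set()
    by_patient = cancerous.groupby("patient_id")["sample_id"].apply(list).to_dict()
    normal_ids = normal.sample_id.tolist()
    order = rng.permutation(len(normal_ids))
    for i in order:
        row = normal.iloc[i]
        group = [row.sample_id]
        for sid in by_patient.get(row.patient_id, []):
            if sid not in claimed and len(group) < 3:
                group.append(sid)
                claimed.add(sid)
        groups.append(group)
    pool = [s for s in cancerous.sample_id if s not in claimed]
    pool = [pool[i] for i in rng.permutation(len(pool))]
    for group in groups:
        while len(group) < 3:
            group.append(pool.pop())

    plan = FoldPlan(
        groups=groups,
        sample_class=dict(zip(df.sample_id, df.tissue_class)),
        sample_patient=dict(zip(df.sample_id, df.patient_id)),
    )
    plan.validate()
    return plan


def confusion_ratio(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Row-normalized 2x2 confusion matrix (rows: true 0/1, cols: predicted)."""
    mat = np.zeros((2, 2))
    for t in (0, 1):
        sel = np.asarray(y_true) == t
        n = int(sel.sum())
        if n == 0:
            mat[t] = np.nan
            continue
        for p in (0, 1):
            mat[t, p] = np.sum(np.asarray(y_pred)[sel] == p) / n
    return mat


def aggregate_confusion(per_fold: list[np.ndarray]) -> dict:
    """Cell-wise mean and MSE of row-normalized fold matrices.

    Overall accuracy is the mean of the two diagonal means (the average
    predictive ratio of each true class, equally weighted).
    """
    stack = np.stack([np.asarray(m, dtype=float) for m in per_fold])
    mean = stack.mean(axis=0)
    mse = ((stack - mean) ** 2).mean(axis=0)
    return {
        "mean": mean,
        "mse": mse,
        "overall_accuracy": float(np.mean(np.diag(mean))),
        "n_folds": len(per_fold),
    }


def _fold_seed(seed: int, fold: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, fold, salt]).generate_state(1)[0] % (2**31))


def run_experiment(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Full pipeline: synthesize -> preprocess -> encode -> per-fold
    augment/train/test for the 2D-CNN, 1D-CNN and KNN sweep.

    Returns a report dict with per-fold row-normalized confusion
    matrices, per-model aggregates for the train/val/test streams, and a
    model-comparison summary table of overall accuracies.
    """
    if config is None:
        config = profile_config("fast")
    if seed is None:
        seed = config.seed

    grid = WavenumberGrid(config.grid.start, config.grid.stop, config.grid.n_channels)
    cohort = synth_cohort(
        CohortConfig(
            n_cancerous=config.cohort.n_cancerous,
            n_normal=config.cohort.n_normal,
            n_paracancerous=config.cohort.n_paracancerous,
            points_per_sample=config.cohort.points_per_sample,
            protein_fraction=config.cohort.protein_fraction,
            baseline_scale_sigma=config.cohort.baseline_scale_sigma,
            grid=grid,
        ),
        seed=seed,
    )
    pre = preprocess_cohort(
        cohort,
        poly_order=config.preprocess.poly_order,
        max_iter=config.preprocess.max_iter,
        tol=config.preprocess.tol,
    )
    return run_experiment_on(pre, config, seed)


def run_experiment_on(pre: Cohort, config: PipelineConfig, seed: int) -> dict:
    """Run the discrimination experiment on an already preprocessed cohort."""
    labelled = [s for s in pre.series if s.tissue_class in LABELS]
    images = encode_cohort(
        pre,
        n_levels=config.encode.n_levels,
        clip_lo_pct=config.encode.clip_lo_pct,
        clip_hi_pct=config.encode.clip_hi_pct,
    )
    X_img = np.stack([im.pixels for im in images]).astype(np.float32)
    X_spec = np.stack([s.conventional.intensities for s in labelled]).astype(np.float32)
    y = np.array([im.label for im in images], dtype=np.int64)
    sample_ids = np.array([im.sample_id for im in images])

    plan = grouped_kfold(pd.DataFrame(pre.sample_table()), k=config.experiment.n_folds, seed=seed)
    n_run = config.experiment.folds_to_run or plan.k

    folds: dict[str, dict[str, list[np.ndarray]]] = {}
    knn_folds: dict[int, dict[str, list[np.ndarray]]] = {
        k: {"train": [], "val": [], "test": []} for k in config.experiment.knn_k_values
    }

    def record(model: str, split: str, mat: np.ndarray) -> None:
        folds.setdefault(model, {}).setdefault(split, []).append(mat)

    for fi, group in enumerate(plan.groups[:n_run]):
        test_mask = np.isin(sample_ids, group)
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        # leakage guard: augmentation sources must be training samples only
        assert not (set(sample_ids[train_idx]) & set(group))

        aug_seed = _fold_seed(seed, fi, 1)
        Xa, ya, manifest = expand_to_n(
            X_img[train_idx], y[train_idx],
            n_per_class=config.augment.n_per_class,
            seed=aug_seed,
            noise_sigma=config.augment.noise_sigma,
        )
        assert manifest.source.max() < len(train_idx)
        tr, va = split_train_val(Xa, ya, config.augment.train_ratio, aug_seed)

        m2 = config.cnn2d
        cnn2d = CNN2DClassifier(
            conv_channels=tuple(m2.conv_channels), kernel_size=m2.kernel_size,
            fc_width=m2.fc_width, dropout=m2.dropout, leaky_slope=m2.leaky_slope,
            lr=m2.lr, lr_min=m2.lr_min, batch_size=m2.batch_size, max_iters=m2.max_iters,
            eval_every=m2.eval_every, patience=m2.patience, min_delta=m2.min_delta,
            random_state=_fold_seed(seed, fi, 2),
        )
        cnn2d.fit(Xa[tr], ya[tr], X_val=Xa[va], y_val=ya[va])
        record("cnn2d", "train", confusion_ratio(ya[tr], cnn2d.predict(Xa[tr])))
        record("cnn2d", "val", confusion_ratio(ya[va], cnn2d.predict(Xa[va])))
        record("cnn2d", "test", confusion_ratio(y[test_idx], cnn2d.predict(X_img[test_idx])))

        if config.experiment.run_cnn1d:
            Xs, ys, _ = expand_spectra_to_n(
                X_spec[train_idx], y[train_idx],
                n_per_class=config.augment.n_per_class,
                seed=aug_seed,
                noise_sigma=config.augment.noise_sigma,
            )
            tr1, va1 = split_train_val(Xs, ys, config.augment.train_ratio, aug_seed)
            m1 = config.cnn1d
            cnn1d = CNN1DClassifier(
                conv_channels=tuple(m1.conv_channels), kernel_size=m1.kernel_size,
                fc_width=m1.fc_width, dropout=m1.dropout, leaky_slope=m1.leaky_slope,
                lr=m1.lr, lr_min=m1.lr_min, batch_size=m1.batch_size, max_iters=m1.max_iters,
                eval_every=m1.eval_every, patience=m1.patience, min_delta=m1.min_delta,
                random_state=_fold_seed(seed, fi, 3),
            )
            cnn1d.fit(Xs[tr1], ys[tr1], X_val=Xs[va1], y_val=ys[va1])
            record("cnn1d", "train", confusion_ratio(ys[tr1], cnn1d.predict(Xs[tr1])))
            record("cnn1d", "val", confusion_ratio(ys[va1], cnn1d.predict(Xs[va1])))
            record("cnn1d", "test", confusion_ratio(y[test_idx], cnn1d.predict(X_spec[test_idx])))

        if config.experiment.run_knn:
            flat = Xa.reshape(len(Xa), -1)
            for kval in config.experiment.knn_k_values:
                knn = KNNImageClassifier(n_neighbors=kval).fit(flat[tr], ya[tr])
                knn_folds[kval]["train"].append(confusion_ratio(ya[tr], knn.predict(flat[tr])))
                knn_folds[kval]["val"].append(confusion_ratio(ya[va], knn.predict(flat[va])))
                knn_folds[kval]["test"].append(
                    confusion_ratio(y[test_idx], knn.predict(X_img[test_idx].reshape(len(test_idx), -1)))
                )

    aggregates = {
        model: {split: aggregate_confusion(mats) for split, mats in splits.items()}
        for model, splits in folds.items()
    }
    knn_aggregates = {
        kval: {split: aggregate_confusion(mats) for split, mats in splits.items() if mats}
        for kval, splits in knn_folds.items()
        if any(knn_folds[kval].values())
    }

    summary_rows = []
    for model, agg in aggregates.items():
        summary_rows.append(
            {
                "model": model,
                **{s: agg[s]["overall_accuracy"] for s in ("train", "val", "test")},
            }
        )
    for kval, agg in knn_aggregates.items():
        if agg:
            summary_rows.append(
                {
                    "model": f"knn_k{kval}",
                    **{s: agg[s]["overall_accuracy"] for s in ("train", "val", "test")},
                }
            )

    return {
        "seed": seed,
        "profile": config.profile,
        "n_images": len(y),
        "n_folds_run": n_run,
        "fold_plan": plan.groups,
        "folds": folds,
        "knn_folds": knn_folds,
        "aggregates": aggregates,
        "knn_aggregates": knn_aggregates,
        "summary": pd.DataFrame(summary_rows),
    }
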