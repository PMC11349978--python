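"""Metrics, fold planning and end-to-end experiment orchestration.

Detection and grading rates follow the truncation convention: percentages
are floored to one decimal (98.36% prints as 98.3%), computed exactly with
rational arithmetic.  Sensitivity/specificity/accuracy are count-agnostic
and applied at pixel level (segmentation) and image level (classification)
alike.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifier import DualCNNClassifier, NearestPatternGrader
from .enhancement import alhe_enhance
from .features import build_mfm, morph_feature_vector
from .fusion import fuse_images
from .segmentation import segment_knee_joint

__all__ = [
    "ConfusionCounts",
    "RateReport",
    "FoldPlan",
    "compute_sensitivity_specificity_accuracy",
    "detection_rate",
    "grading_rate",
    "roc_area",
    "mse",
    "kfold_plan",
    "ExperimentConfig",
    "preprocess_sample",
    "run_experiment",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class RateReport:
    """A correct/total ratio reported as a truncated one-decimal percentage."""

    numerator: int
    denominator: int
    rate_percent: float = field(init=False)

    def __post_init__(self):
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")
        if self.denominator < 1:
            raise ValueError("denominator must be >= 1")
        # exact truncation to one decimal via rational arithmetic
        self.rate_percent = float(Fraction(1000 * self.numerator, self.denominator) // 1) / 10.0


@dataclass
class FoldPlan:
    k: int
    assignments: np.ndarray  # fold index per sample
    train_fraction: float


def compute_sensitivity_specificity_accuracy(
    counts: ConfusionCounts,
) -> tuple[float, float, float]:
    """Se, Sp, Acc in percent; a zero denominator yields NaN for that metric."""
    se = 100.0 * counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else float("nan")
    sp = 100.0 * counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else float("nan")
    total = counts.TP + counts.TN + counts.FP + counts.FN
    acc = 100.0 * (counts.TP + counts.TN) / total if total else float("nan")
    return se, sp, acc


def detection_rate(correct: int, total: int) -> RateReport:
    """Knee detection rate: correctly detected images over total, truncated."""
    return RateReport(correct, total)


def grading_rate(
    per_grade_counts: dict[int, tuple[int, int]],
) -> tuple[dict[int, RateReport], RateReport]:
    """Per-grade and average grading rates.

    The average is pooled: total correct over total images across grades,
    then truncated.
    """
    if not per_grade_counts:
        raise ValueError("per_grade_counts is empty")
    per_grade = {g: RateReport(c, t) for g, (c, t) in sorted(per_grade_counts.items())}
    total_correct = sum(c for c, _ in per_grade_counts.values())
    total = sum(t for _, t in per_grade_counts.values())
    return per_grade, RateReport(total_correct, total)


def roc_area(scores, labels) -> float:
    """Trapezoidal ROC AUC (equals the Mann-Whitney rank statistic)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute an ROC area")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def mse(predicted: np.ndarray, one_hot_targets: np.ndarray) -> float:
    """Mean squared elementwise difference between probabilities and targets."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(one_hot_targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def kfold_plan(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold assignment, deterministic for a fixed seed."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(labels) < k:
        raise ValueError("dataset smaller than k")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, train_fraction=1.0 - 1.0 / k)


# ---------------------------------------------------------------------------
# end-to-end experiment


@dataclass
class ExperimentConfig:
    k: int = 5
    seed: int = 0
    region_size: int = 5
    tile_size: int = 16
    width_multiplier: float = 0.25
    epochs: int = 25
    batch_size: int = 16
    lr: float = 0.01
    gao_iterations: int = 40
    folds_to_run: int | None = None  # None = all k folds

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def preprocess_sample(sample, config: ExperimentConfig):
    """Enhance both views, fuse, segment and featurise one phantom."""
    e1 = alhe_enhance(sample.view1, region_size=config.region_size)
    e2 = alhe_enhance(sample.view2, region_size=config.region_size)
    fused = fuse_images(e1, e2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        region = segment_knee_joint(fused)
    mfm = build_mfm(fused, region.mask, tile_size=config.tile_size, standardize=False)
    if region.area > 0:
        fvec = morph_feature_vector(fused, region.mask)
    else:
        fvec = np.zeros(6)
    pixel_acc = float((region.mask == sample.truth_mask).mean())
    return fused, mfm.grid, fvec, pixel_acc


def run_experiment(samples, config: ExperimentConfig | None = None) -> dict:
    """Full train/test flow over a phantom dataset with k-fold validation.

    Per fold: train the dual CNN backbone on the training split, refine the
    final dense layer with GAO, and report Se/Sp/Acc, detection rates, ROC
    area and MSE on the held-out fold; fit the nearest-pattern grader on
    the OA training samples and report per-grade grading rates on the OA
    test samples.  Returns a JSON-serialisable report.
    """
    if config is None:
        config = ExperimentConfig()
    labels = np.array([0 if s.label == "normal" else 1 for s in samples])
    grades = np.array([s.grade for s in samples])
    if (labels == 1).any() and np.unique(grades[labels == 1]).size < 4:
        raise ValueError("OA samples must cover grades 1-4 for grading")

    pre = [preprocess_sample(s, config) for s in samples]
    images = np.stack([p[0] for p in pre])
    mfms = np.stack([p[1] for p in pre])
    fvecs = np.stack([p[2] for p in pre])
    seg_acc = np.array([p[3] for p in pre])

    plan = kfold_plan(labels, k=config.k, seed=config.seed)
    n_folds = config.k if config.folds_to_run is None else min(config.folds_to_run, config.k)
    fold_rows = []
    pooled = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    pooled_grades: dict[int, list[int]] = {g: [0, 0] for g in (1, 2, 3, 4)}
    for fold in range(n_folds):
        test = plan.assignments == fold
        train = ~test
        clf = DualCNNClassifier(
            input_size=images.shape[1],
            width_multiplier=config.width_multiplier,
            mfm_grid=mfms.shape[1:3],
            epochs=config.epochs,
            batch_size=config.batch_size,
            lr=config.lr,
            gao_iterations=config.gao_iterations,
            seed=config.seed + fold,
        )
        clf.fit((images[train], mfms[train]), labels[train])
        probs = clf.predict_proba((images[test], mfms[test]))
        pred = probs.argmax(axis=1)
        truth = labels[test]
        counts = ConfusionCounts(
            TP=int(((pred == 1) & (truth == 1)).sum()),
            TN=int(((pred == 0) & (truth == 0)).sum()),
            FP=int(((pred == 1) & (truth == 0)).sum()),
            FN=int(((pred == 0) & (truth == 1)).sum()),
        )
        se, sp, acc = compute_sensitivity_specificity_accuracy(counts)
        pooled["tp"] += counts.TP
        pooled["tn"] += counts.TN
        pooled["fp"] += counts.FP
        pooled["fn"] += counts.FN

        grader = NearestPatternGrader().fit(fvecs[train & (labels == 1)], grades[train & (labels == 1)])
        oa_test = test & (labels == 1)
        g_pred = grader.predict(fvecs[oa_test])
        for g_true, g_hat in zip(grades[oa_test], g_pred):
            pooled_grades[int(g_true)][1] += 1
            if g_true == g_hat:
                pooled_grades[int(g_true)][0] += 1

        fold_rows.append(
            {
                "fold": fold,
                "n_train": int(train.sum()),
                "n_test": int(test.sum()),
                "sensitivity_percent": se,
                "specificity_percent": sp,
                "accuracy_percent": acc,
                "nkdr_percent": detection_rate(counts.TN, counts.TN + counts.FP).rate_percent,
                "okdr_percent": detection_rate(counts.TP, counts.TP + counts.FN).rate_percent,
                "kdr_percent": detection_rate(
                    counts.TP + counts.TN, counts.TP + counts.TN + counts.FP + counts.FN
                ).rate_percent,
                "roc_auc": roc_area(probs[:, 1], truth),
                "mse": mse(probs, np.eye(2)[truth]),
                "grading_accuracy": float((g_pred == grades[oa_test]).mean()) if oa_test.any() else float("nan"),
                "pre_tuning_val_fitness": getattr(clf, "pre_tuning_val_fitness_", None),
                "post_tuning_val_fitness": getattr(clf, "val_fitness_", None),
            }
        )

    per_grade, avg = grading_rate({g: tuple(v) for g, v in pooled_grades.items() if v[1] > 0}) if any(
        v[1] for v in pooled_grades.values()
    ) else ({}, None)
    report = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_samples": len(samples),
        "segmentation_pixel_accuracy": float(seg_acc.mean()),
        "folds": fold_rows,
        "aggregate": {
            "sensitivity_percent": float(np.nanmean([r["sensitivity_percent"] for r in fold_rows])),
            "specificity_percent": float(np.nanmean([r["specificity_percent"] for r in fold_rows])),
            "accuracy_percent": float(np.nanmean([r["accuracy_percent"] for r in fold_rows])),
            "roc_auc": float(np.nanmean([r["roc_auc"] for r in fold_rows])),
            "mse": float(np.nanmean([r["mse"] for r in fold_rows])),
            "kdr_percent": detection_rate(
                pooled["tp"] + pooled["tn"], sum(pooled.values())
            ).rate_percent if sum(pooled.values()) else float("nan"),
            "grading_rate_percent": avg.rate_percent if avg else float("nan"),
            "per_grade_rate_percent": {g: r.rate_percent for g, r in per_grade.items()},
        },
    }
    return report


def write_report(report: dict, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    """Persist a run_experiment report as JSON (and per-fold CSV)."""
    Path(json_path).write_text(json.dumps(report, indent=2))
    if csv_path is not None:
        pd.DataFrame(report["folds"]).to_csv(csv_path, index=False)
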