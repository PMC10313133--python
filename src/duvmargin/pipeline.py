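"""End-to-end orchestration: tile -> features -> classify -> explain -> fuse -> evaluate.

The cross-validation loop is grouped at the patient level; patch features are
extracted once per slide and reused across folds, with flip/rotation
augmentation applied to training folds only.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

from duvmargin import backbone as bb
from duvmargin import evaluation, fusion, gradcampp, patch_classifier, phantom, tiling

logger = logging.getLogger("duvmargin")

__all__ = [
    "PipelineConfig",
    "SlidePrediction",
    "PipelineResult",
    "run_pipeline",
    "cross_validate_cohort",
    "render_overlay",
]

MALIGNANT = 1
BENIGN = -1


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run; embedded in every output artifact."""

    patch_size: int = 400
    foreground_threshold: float = 0.2
    background_threshold: float = 5.0
    backbone: str = "mock"
    feature_dim: int = 16
    augment: bool = True
    importance_threshold: float = 0.25
    q: float = 0.0
    k_folds: int = 5
    seed: int = 0
    n_benign: int = 24
    n_malignant: int = 36
    phantom_height: int = 1200
    phantom_width: int = 1600
    cam_input_size: int = 256
    cam_class: int | None = gradcampp.MALIGNANT_CLASS
    classifier_backend: str = "sklearn"

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not 0.0 <= self.importance_threshold <= 1.0:
            raise ValueError("importance_threshold must lie in [0, 1]")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def tiling(self) -> tiling.TilingConfig:
        return tiling.TilingConfig(
            patch_size=self.patch_size,
            foreground_threshold=self.foreground_threshold,
            background_threshold=self.background_threshold,
        )


@dataclass
class SlidePrediction:
    """Per-slide outcome of one cross-validation run."""

    slide_id: str
    patient_id: str
    fold: int
    label: int
    fused_label: int
    majority_label: int
    score: float  # H_i / M_i
    fusion_result: fusion.FusionResult


@dataclass
class PipelineResult:
    config: PipelineConfig
    report: evaluation.EvalReport
    predictions: list[SlidePrediction]
    majority_report: evaluation.EvalReport


def _patch_truth_labels(patch_set: tiling.PatchSet, truth: phantom.PhantomTruth | None) -> np.ndarray:
    """Ground-truth label per valid patch: phantom tissue majority when
    available, otherwise the slide label (annotation-free fallback)."""
    labels = np.empty(patch_set.n_valid, dtype=int)
    for j, patch in enumerate(patch_set.patches):
        if truth is not None and truth.tissue_grid[patch.row, patch.col] != 0:
            labels[j] = truth.tissue_grid[patch.row, patch.col]
        else:
            labels[j] = patch_set.label
    return labels


@dataclass
class _SlideCache:
    patch_set: tiling.PatchSet
    truth_labels: np.ndarray
    features: np.ndarray  # (M_i, D) in patch order
    augmented_features: np.ndarray | None  # (6 * M_i, D) for training
    augmented_labels: np.ndarray | None


def _prepare_slide(
    item: "phantom.CohortSlide | tuple[tiling.SlideRecord, phantom.PhantomTruth | None]",
    config: PipelineConfig,
    extractor,
) -> _SlideCache:
    if isinstance(item, phantom.CohortSlide):
        slide, truth = item.slide, item.truth
    else:
        slide, truth = item
    patch_set = tiling.extract_valid_patches(slide, config.tiling())
    truth_labels = _patch_truth_labels(patch_set, truth)
    if patch_set.n_valid:
        features = np.vstack([extractor(p.pixels) for p in patch_set.patches])
    else:
        features = np.empty((0, extractor.spec.feature_dim))
    aug_features = aug_labels = None
    if config.augment and patch_set.n_valid:
        feats, labs = [], []
        for patch, label in zip(patch_set.patches, truth_labels):
            for variant in patch_classifier.augment_patch(patch.pixels):
                feats.append(extractor(variant))
                labs.append(label)
        aug_features = np.vstack(feats)
        aug_labels = np.asarray(labs)
    return _SlideCache(
        patch_set=patch_set,
        truth_labels=truth_labels,
        features=features,
        augmented_features=aug_features,
        augmented_labels=aug_labels,
    )


def cross_validate_cohort(
    cohort: list[phantom.CohortSlide], config: PipelineConfig
) -> PipelineResult:
    """Grouped stratified k-fold cross-validation of the full pipeline."""
    if not cohort:
        raise ValueError("cohort is empty")
    extractor = bb.get_backbone(config.backbone, seed=config.seed, feature_dim=config.feature_dim)
    cam_model = gradcampp.build_color_cam_model(input_size=config.cam_input_size)

    logger.info(
        "pipeline thresholds: foreground=%s background=%s importance=%s q=%s",
        config.foreground_threshold,
        config.background_threshold,
        config.importance_threshold,
        config.q,
    )
    caches = [_prepare_slide(item, config, extractor) for item in cohort]
    slide_labels = np.array([item.slide.label for item in cohort])
    patients = np.array([item.slide.patient_id for item in cohort])
    folds = evaluation.grouped_stratified_kfold(
        slide_labels, patients, k=config.k_folds, seed=config.seed
    )

    predictions: list[SlidePrediction] = []
    fold_summaries: list[dict] = []
    for fold in range(config.k_folds):
        train_idx = np.flatnonzero(folds != fold)
        test_idx = np.flatnonzero(folds == fold)
        feats, labels = [], []
        for i in train_idx:
            cache = caches[i]
            if cache.patch_set.n_valid == 0:
                continue
            if config.augment:
                feats.append(cache.augmented_features)
                labels.append(cache.augmented_labels)
            else:
                feats.append(cache.features)
                labels.append(cache.truth_labels)
        model = patch_classifier.train_patch_classifier(
            np.vstack(feats),
            np.concatenate(labels),
            patch_classifier.ClassifierConfig(backend=config.classifier_backend, seed=config.seed),
        )

        for i in test_idx:
            item, cache = cohort[i], caches[i]
            patch_set = cache.patch_set
            if patch_set.n_valid == 0:
                logger.warning("slide %s has no valid patches; calling benign", item.slide.slide_id)
                continue
            preds = patch_classifier.predict_patches(model, cache.features)
            pred_labels = np.array([p.label for p in preds])
            resized = tiling.resize_slide(
                item.slide.pixels, patch_set.plan.resized_h, patch_set.plan.resized_w
            )
            with warnings.catch_warnings():
                # benign slides legitimately yield flat malignant-class maps
                warnings.filterwarnings("ignore", message="importance map is flat")
                imap = gradcampp.regional_importance(
                    cam_model, resized, class_c=config.cam_class, out_shape=resized.shape[:2]
                )
            if imap.all_zero:
                logger.debug("slide %s: flat importance map", item.slide.slide_id)
            fused = fusion.fuse_patch_set(
                [p.row for p in patch_set.patches],
                [p.col for p in patch_set.patches],
                pred_labels,
                imap.values,
                config.patch_size,
                q=config.q,
                threshold=config.importance_threshold,
            )
            predictions.append(
                SlidePrediction(
                    slide_id=item.slide.slide_id,
                    patient_id=item.slide.patient_id,
                    fold=fold,
                    label=item.slide.label,
                    fused_label=fused.slide_label,
                    majority_label=fusion.majority_vote(pred_labels),
                    score=fused.h / fused.m,
                    fusion_result=fused,
                )
            )
        fold_true = [p.label for p in predictions if p.fold == fold]
        fold_pred = [p.fused_label for p in predictions if p.fold == fold]
        tp, tn, fp, fn = evaluation.confusion_counts(fold_true, fold_pred)
        fold_metrics = evaluation.performance_metrics(tp, tn, fp, fn)
        fold_summaries.append(
            {
                "fold": fold,
                "n": len(fold_true),
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "accuracy": fold_metrics.accuracy,
                "sensitivity": fold_metrics.sensitivity,
                "specificity": fold_metrics.specificity,
            }
        )

    report = _build_report(predictions, fold_summaries, fused=True)
    majority_report = _build_report(predictions, [], fused=False)
    return PipelineResult(
        config=config,
        report=report,
        predictions=predictions,
        majority_report=majority_report,
    )


def _build_report(
    predictions: list[SlidePrediction], fold_summaries: list[dict], fused: bool
) -> evaluation.EvalReport:
    y_true = np.array([p.label for p in predictions])
    y_pred = np.array([p.fused_label if fused else p.majority_label for p in predictions])
    tp, tn, fp, fn = evaluation.confusion_counts(y_true, y_pred)
    metrics = evaluation.performance_metrics(tp, tn, fp, fn)
    roc_points: list[tuple[float, float]] = []
    auc = None
    if fused and len(set(y_true.tolist())) == 2:
        scores = np.array([p.score for p in predictions])
        roc_points, auc = evaluation.roc_auc(scores, y_true)
    return evaluation.EvalReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        metrics=metrics,
        roc_points=roc_points,
        auc=auc,
        folds=fold_summaries,
    )


def run_pipeline(
    config: PipelineConfig,
    cohort: list[phantom.CohortSlide] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline, generating a phantom cohort when none is given.

    When ``out_dir`` is set, the cohort manifest, per-patch fusion report,
    evaluation report and the exact configuration are persisted there.
    """
    if cohort is None:
        cohort = phantom.generate_cohort(
            n_benign=config.n_benign,
            n_malignant=config.n_malignant,
            seed=config.seed,
            height=config.phantom_height,
            width=config.phantom_width,
            patch_size=config.patch_size,
        )
    result = cross_validate_cohort(cohort, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        pd.DataFrame(
            [
                {
                    "slide_id": p.slide_id,
                    "patient_id": p.patient_id,
                    "fold": p.fold,
                    "label": p.label,
                    "fused_label": p.fused_label,
                    "majority_label": p.majority_label,
                    "score": p.score,
                }
            for p in result.predictions
            ]
        ).to_csv(out_dir / "slide_predictions.csv", index=False)
        fusion.write_fusion_report(
            {p.slide_id: p.fusion_result for p in result.predictions},
            out_dir / "fusion_report.csv",
        )
        result.report.to_json(out_dir / "evaluation.json")
        result.majority_report.to_json(out_dir / "evaluation_majority_vote.json")
    return result


def render_overlay(
    slide_pixels: np.ndarray,
    fused: fusion.FusionResult,
    patch_size: int,
    scale: float = 0.25,
) -> Image.Image:
    """Overlay patch boxes on a slide: red = malignant, green = benign.

    Only patches with non-zero importance weight are boxed; the image is
    scaled down for viewing.
    """
    if fused.rows is None or fused.cols is None:
        raise ValueError("fusion result carries no grid positions")
    pixels = np.asarray(slide_pixels, dtype=np.uint8)
    image = Image.fromarray(pixels, mode="RGB")
    draw = ImageDraw.Draw(image)
    h, w = pixels.shape[:2]
    for j in range(fused.m):
        r, c = int(fused.rows[j]), int(fused.cols[j])
        top, left = r * patch_size, c * patch_size
        if top + patch_size > h or left + patch_size > w:
            raise ValueError(f"patch ({r}, {c}) does not align with slide of shape {(h, w)}")
        if fused.w[j] <= 0:
            continue
        color = (255, 0, 0) if fused.labels[j] == MALIGNANT else (0, 255, 0)
        draw.rectangle(
            [left, top, left + patch_size - 1, top + patch_size - 1], outline=color, width=6
        )
    if scale != 1.0:
        image = image.resize((max(1, int(w * scale)), max(1, int(h * scale))), Image.BILINEAR)
    return image
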