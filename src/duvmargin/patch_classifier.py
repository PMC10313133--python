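"""Gradient-boosted patch classifier on frozen backbone features.

Training data is expanded with flip/rotation augmentation (six variants per
patch: identity, horizontal flip, vertical flip, and the three non-trivial
90-degree rotations).  Augmentation is applied at training time only; labels
are strictly {+1 malignant, -1 benign}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchPrediction",
    "ClassifierConfig",
    "PatchClassifier",
    "augment_patch",
    "AUGMENTATION_NAMES",
    "train_patch_classifier",
    "predict_patches",
]

MALIGNANT = 1
BENIGN = -1

#: Names of the six augmentation variants, in output order.
AUGMENTATION_NAMES = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270")


@dataclass(frozen=True)
class PatchPrediction:
    """Binary patch call with its malignant probability.

    ``label`` is +1 exactly when ``score >= threshold`` (score ties go to
    malignant, favoring sensitivity).
    """

    label: int
    score: float


@dataclass(frozen=True)
class ClassifierConfig:
    backend: str = "sklearn"  # "sklearn" or "xgboost"
    seed: int = 0
    decision_threshold: float = 0.5


def augment_patch(pixels: np.ndarray) -> list[np.ndarray]:
    """Six flip/rotation variants of a square patch.

    Returns ``[identity, hflip, vflip, rot90, rot180, rot270]``.  Variants are
    not deduplicated even when they coincide (e.g. on a constant patch), so
    the output length is always six.
    """
    pixels = np.asarray(pixels)
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"augmentation requires a square patch, got shape {pixels.shape}")
    return [
        pixels.copy(),
        np.flip(pixels, axis=1).copy(),
        np.flip(pixels, axis=0).copy(),
        np.rot90(pixels, k=1).copy(),
        np.rot90(pixels, k=2).copy(),
        np.rot90(pixels, k=3).copy(),
    ]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {MALIGNANT, BENIGN}
    if bad:
        raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")
    return labels


class PatchClassifier:
    """Thin wrapper fixing the {+1, -1} label convention and the tie rule."""

    def __init__(self, model, config: ClassifierConfig, feature_dim: int) -> None:
        self._model = model
        self.config = config
        self.feature_dim = feature_dim

    def predict(self, features: np.ndarray) -> list[PatchPrediction]:
        features = np.asarray(features, dtype=np.float64)
        if features.size == 0:
            return []
        if features.ndim != 2 or features.shape[1] != self.feature_dim:
            raise ValueError(
                f"expected (n, {self.feature_dim}) feature matrix, got shape {features.shape}"
            )
        pos_col = int(np.flatnonzero(self._model.classes_ == MALIGNANT)[0])
        scores = self._model.predict_proba(features)[:, pos_col]
        threshold = self.config.decision_threshold
        return [
            PatchPrediction(
                label=MALIGNANT if score >= threshold else BENIGN, score=float(score)
            )
            for score in scores
        ]


def train_patch_classifier(
    features: np.ndarray, labels: np.ndarray, config: ClassifierConfig | None = None
) -> PatchClassifier:
    """Fit a gradient-boosted tree ensemble at library defaults, fixed seed.

    The backend is scikit-learn's histogram gradient boosting by default;
    ``backend="xgboost"`` uses XGBoost at its defaults when installed.  Raises
    on single-class input.
    """
    config = config or ClassifierConfig()
    features = np.asarray(features, dtype=np.float64)
    labels = _check_labels(labels)
    if features.ndim != 2 or len(features) != len(labels):
        raise ValueError("features must be (n, d) aligned with n labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes present in labels")

    if config.backend == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:
            raise ImportError(
                "xgboost backend requested but xgboost is not installed; "
                "use backend='sklearn'"
            ) from exc
        # XGBoost wants {0, 1} targets; the wrapper converts back on predict.
        model = XGBClassifier(random_state=config.seed)
        model.fit(features, (labels == MALIGNANT).astype(int))
        model.classes_ = np.array([BENIGN, MALIGNANT])
    else:
        from sklearn.ensemble import HistGradientBoostingClassifier

        model = HistGradientBoostingClassifier(random_state=config.seed)
        model.fit(features, labels)
    return PatchClassifier(model=model, config=config, feature_dim=features.shape[1])


def predict_patches(model: PatchClassifier, features: np.ndarray) -> list[PatchPrediction]:
    """One prediction per feature row; no augmentation at prediction time."""
    return model.predict(np.asarray(features, dtype=np.float64).reshape(-1, model.feature_dim)
                         if np.asarray(features).size else np.empty((0, model.feature_dim)))
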