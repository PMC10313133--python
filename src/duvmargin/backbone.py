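"""Frozen feature extraction over patches.

Two interchangeable backbones implement one contract: a deterministic
D-vector per patch, computed from fixed weights with no training anywhere.

* :class:`MockBackbone` — per-channel means plus a seeded random projection of
  a downsampled copy of the patch.  Runs everywhere, needs no model download,
  and is the default for tests and phantom experiments.
* :class:`TorchBackbone` — post-global-average-pool activations of a
  pretrained torchvision network (2048-D for ResNet50).  Available only when
  torch/torchvision are installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "BackboneSpec",
    "FeatureVector",
    "MockBackbone",
    "TorchBackbone",
    "RESNET50_SPEC",
    "MOCK_SPEC",
    "get_backbone",
    "extract_features",
    "batch_extract",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Identity and preprocessing contract of a feature extractor."""

    name: str
    input_size: int
    feature_dim: int
    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    std: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")


#: Contract of the pretrained ResNet50 route: 224x224 inputs normalized with
#: ImageNet statistics, 2048-D global-average-pooled final activations.
RESNET50_SPEC = BackboneSpec(
    name="resnet50",
    input_size=224,
    feature_dim=2048,
    mean=(0.485, 0.456, 0.406),
    std=(0.229, 0.224, 0.225),
)

MOCK_SPEC = BackboneSpec(name="mock", input_size=32, feature_dim=16)


@dataclass
class FeatureVector:
    values: np.ndarray
    backbone_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("feature vector must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def _check_patch(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"patch must be HxWx3 RGB, got shape {pixels.shape}")
    return pixels


def _resize_unit(pixels: np.ndarray, size: int) -> np.ndarray:
    """Resize to size x size and scale to [0, 1] floats."""
    if pixels.shape[0] != size or pixels.shape[1] != size:
        image = Image.fromarray(pixels.astype(np.uint8), mode="RGB")
        pixels = np.asarray(image.resize((size, size), Image.BILINEAR))
    return pixels.astype(np.float64) / 255.0


class MockBackbone:
    """Deterministic stand-in backbone: channel means + seeded random projection.

    The first three feature components are the per-channel means of the
    unit-scaled resized patch; the remaining ``feature_dim - 3`` components are
    a fixed Gaussian random projection (drawn once from ``seed``) of the
    flattened 8x8 thumbnail.  A pure function of the patch pixels.
    """

    def __init__(self, feature_dim: int = 16, input_size: int = 32, seed: int = 0) -> None:
        if feature_dim < 3:
            raise ValueError("mock backbone needs feature_dim >= 3 (channel means)")
        self.spec = BackboneSpec(name="mock", input_size=input_size, feature_dim=feature_dim)
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((8 * 8 * 3, feature_dim - 3)) / np.sqrt(8 * 8 * 3)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        pixels = _check_patch(pixels)
        unit = _resize_unit(pixels, self.spec.input_size)
        channel_means = unit.mean(axis=(0, 1))
        thumb = np.asarray(
            Image.fromarray((unit * 255).astype(np.uint8), mode="RGB").resize(
                (8, 8), Image.BILINEAR
            ),
            dtype=np.float64,
        ).ravel() / 255.0
        projected = thumb @ self._projection
        return np.concatenate([channel_means, projected])


class TorchBackbone:
    """Pretrained torchvision backbone, frozen, post-global-average-pool output.

    Optional: requires torch + torchvision (and, for pretrained weights, a
    cached download).  The surrounding pipeline never depends on it.
    """

    def __init__(self, name: str = "resnet50", weights: str | None = "DEFAULT") -> None:
        try:
            import torch
            import torchvision.models as models
        except ImportError as exc:  # pragma: no cover - torch not in test env
            raise ImportError(
                "TorchBackbone requires torch and torchvision; install the "
                "'torch' extra or use MockBackbone"
            ) from exc
        factory = getattr(models, name, None)
        if factory is None:  # pragma: no cover
            raise ValueError(f"unknown torchvision model: {name}")
        net = factory(weights=weights)
        net.eval()
        for p in net.parameters():
            p.requires_grad_(False)
        # Drop the classifier head: keep activations after global average pooling.
        self._torch = torch
        self._features = torch.nn.Sequential(*list(net.children())[:-1])
        dim = 2048 if name == "resnet50" else net.fc.in_features
        self.spec = BackboneSpec(
            name=name,
            input_size=224,
            feature_dim=dim,
            mean=(0.485, 0.456, 0.406),
            std=(0.229, 0.224, 0.225),
        )

    def __call__(self, pixels: np.ndarray) -> np.ndarray:  # pragma: no cover
        pixels = _check_patch(pixels)
        unit = _resize_unit(pixels, self.spec.input_size)
        unit = (unit - np.array(self.spec.mean)) / np.array(self.spec.std)
        tensor = self._torch.from_numpy(unit.transpose(2, 0, 1)[None]).float()
        with self._torch.no_grad():
            out = self._features(tensor)
        return out.numpy().reshape(-1).astype(np.float64)


def get_backbone(name: str, seed: int = 0, feature_dim: int = 16):
    """Factory keyed by backbone name ('mock' or a torchvision model name)."""
    if name == "mock":
        return MockBackbone(feature_dim=feature_dim, seed=seed)
    return TorchBackbone(name=name)


def extract_features(patch_pixels: np.ndarray, backbone) -> FeatureVector:
    """Run one patch through a backbone; deterministic for fixed weights."""
    return FeatureVector(values=backbone(patch_pixels), backbone_id=backbone.spec.name)


def batch_extract(patches, backbone, keys: list[tuple] | None = None) -> pd.DataFrame:
    """Feature table with one row per patch, order-stable.

    ``patches`` is an iterable of pixel arrays (or objects with a ``pixels``
    attribute).  ``keys`` optionally provides (slide_id, row, col) index
    tuples aligned with the patches.
    """
    rows = []
    for patch in patches:
        pixels = getattr(patch, "pixels", patch)
        rows.append(backbone(pixels))
    if not rows:
        table = pd.DataFrame(
            np.empty((0, backbone.spec.feature_dim)),
            columns=[f"f{i}" for i in range(backbone.spec.feature_dim)],
        )
    else:
        table = pd.DataFrame(np.vstack(rows), columns=[f"f{i}" for i in range(len(rows[0]))])
    if keys is not None:
        if len(keys) != len(table):
            raise ValueError("keys must align one-to-one with patches")
        table.index = pd.MultiIndex.from_tuples(keys, names=["slide_id", "row", "col"])
    return table
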