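"""Non-overlapping grid tiling of whole-surface images with foreground filtering.

A slide is resized (bilinear) to the nearest dimensions divisible by the patch
size, converted to grayscale, and split into a disjoint grid of
``patch_size x patch_size`` tiles.  A tile is *valid* when the fraction of its
pixels whose luma clears the background threshold reaches the foreground
threshold; only valid tiles move on to feature extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SlideRecord",
    "GridPlan",
    "PatchRecord",
    "PatchSet",
    "TilingConfig",
    "plan_grid",
    "to_grayscale",
    "foreground_fraction",
    "resize_slide",
    "extract_valid_patches",
    "read_slide",
    "write_patches",
]

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

MALIGNANT = 1
BENIGN = -1


@dataclass(frozen=True)
class TilingConfig:
    """Knobs of the tiling stage.

    ``foreground_threshold`` is the minimum fraction of foreground pixels for a
    patch to be valid; ``background_threshold`` is the minimum luma for a pixel
    to count as foreground (compared with ``>=``).
    """

    patch_size: int = 400
    foreground_threshold: float = 0.2
    background_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError(f"patch_size must be >= 1, got {self.patch_size}")
        if not 0.0 <= self.foreground_threshold <= 1.0:
            raise ValueError(
                f"foreground_threshold must lie in [0, 1], got {self.foreground_threshold}"
            )


@dataclass
class SlideRecord:
    """One RGB whole-surface image with its slide-level label and patient id."""

    slide_id: str
    patient_id: str
    pixels: np.ndarray  # H x W x 3, uint8
    label: int  # +1 malignant, -1 benign

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"slide pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("slide must have at least one pixel")
        if self.label not in (MALIGNANT, BENIGN):
            raise ValueError(f"label must be +1 or -1, got {self.label}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class GridPlan:
    """Resized dimensions and grid layout for one slide."""

    resized_h: int
    resized_w: int
    rows: int
    cols: int
    patch_size: int

    def __post_init__(self) -> None:
        if self.resized_h != self.rows * self.patch_size:
            raise ValueError("resized_h must equal rows * patch_size")
        if self.resized_w != self.cols * self.patch_size:
            raise ValueError("resized_w must equal cols * patch_size")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must contain at least one patch")

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols


@dataclass
class PatchRecord:
    """One grid tile: pixel content, grid position and foreground statistics."""

    row: int
    col: int
    pixels: np.ndarray  # patch_size x patch_size x 3, uint8
    foreground_fraction: float
    valid: bool


@dataclass
class PatchSet:
    """Valid patches of one slide together with the grid plan used.

    ``fractions`` keeps the foreground fraction for *every* grid cell (rows x
    cols) so that diagnostics and rendering can reason about rejected cells;
    ``patches`` holds only the valid tiles.
    """

    slide_id: str
    patient_id: str
    label: int
    plan: GridPlan
    patches: list[PatchRecord] = field(default_factory=list)
    fractions: np.ndarray | None = None

    @property
    def n_valid(self) -> int:
        """Count of valid foreground patches (``M_i``)."""
        return len(self.patches)


def _round_to_multiple(value: int, base: int) -> int:
    """Nearest positive multiple of ``base``; exact halves round up."""
    multiples = math.floor(value / base + 0.5)
    return max(multiples, 1) * base


def plan_grid(height: int, width: int, patch_size: int = 400) -> GridPlan:
    """Plan the non-overlapping grid for a slide of the given dimensions.

    The slide is (virtually) resized to the nearest multiples of
    ``patch_size``; a dimension exactly halfway between two multiples rounds
    up, and a dimension below half a patch still yields one patch.
    """
    if height < 1 or width < 1 or patch_size < 1:
        raise ValueError(
            f"height, width and patch_size must be >= 1, got ({height}, {width}, {patch_size})"
        )
    resized_h = _round_to_multiple(int(height), int(patch_size))
    resized_w = _round_to_multiple(int(width), int(patch_size))
    return GridPlan(
        resized_h=resized_h,
        resized_w=resized_w,
        rows=resized_h // patch_size,
        cols=resized_w // patch_size,
        patch_size=int(patch_size),
    )


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """BT.601 luma (0.299 R + 0.587 G + 0.114 B) kept as unrounded floats."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB input, got shape {pixels.shape}")
    return pixels.astype(np.float64) @ LUMA_WEIGHTS


def foreground_fraction(gray_patch: np.ndarray, background_threshold: float = 5.0) -> float:
    """Fraction of pixels with luma >= ``background_threshold``."""
    gray_patch = np.asarray(gray_patch)
    if gray_patch.size == 0:
        raise ValueError("cannot compute foreground fraction of an empty patch")
    return float(np.mean(gray_patch >= background_threshold))


def resize_slide(pixels: np.ndarray, resized_h: int, resized_w: int) -> np.ndarray:
    """Bilinear resize to (resized_h, resized_w); identity when dims already match."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    if pixels.shape[0] == resized_h and pixels.shape[1] == resized_w:
        return pixels
    image = Image.fromarray(pixels, mode="RGB")
    return np.asarray(image.resize((resized_w, resized_h), Image.BILINEAR))


def extract_valid_patches(slide: SlideRecord, config: TilingConfig | None = None) -> PatchSet:
    """Resize a slide onto its grid plan and keep the foreground-valid patches.

    Returns a :class:`PatchSet` whose ``patches`` list contains exactly the
    tiles whose foreground fraction reaches ``config.foreground_threshold``,
    in row-major grid order.
    """
    config = config or TilingConfig()
    plan = plan_grid(slide.height, slide.width, config.patch_size)
    resized = resize_slide(slide.pixels, plan.resized_h, plan.resized_w)
    gray = to_grayscale(resized)

    p = plan.patch_size
    fractions = np.empty((plan.rows, plan.cols), dtype=np.float64)
    patches: list[PatchRecord] = []
    for r in range(plan.rows):
        for c in range(plan.cols):
            tile_gray = gray[r * p : (r + 1) * p, c * p : (c + 1) * p]
            frac = foreground_fraction(tile_gray, config.background_threshold)
            fractions[r, c] = frac
            if frac >= config.foreground_threshold:
                patches.append(
                    PatchRecord(
                        row=r,
                        col=c,
                        pixels=resized[r * p : (r + 1) * p, c * p : (c + 1) * p],
                        foreground_fraction=frac,
                        valid=True,
                    )
                )
    return PatchSet(
        slide_id=slide.slide_id,
        patient_id=slide.patient_id,
        label=slide.label,
        plan=plan,
        patches=patches,
        fractions=fractions,
    )


def read_slide(path: str | Path, slide_id: str, patient_id: str, label: int) -> SlideRecord:
    """Load a PNG/TIFF RGB slide from disk into a :class:`SlideRecord`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"slide image not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        pixels = np.asarray(tifffile.imread(path))
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    return SlideRecord(slide_id=slide_id, patient_id=patient_id, pixels=pixels, label=label)


def write_patches(patch_set: PatchSet, out_dir: str | Path) -> pd.DataFrame:
    """Write valid patches as PNGs plus a per-slide patch manifest CSV.

    Patch files are named ``{slide_id}_r{row}_c{col}.png``; the manifest lists
    slide_id, patient_id, row, col, foreground_fraction and the slide label.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patch in patch_set.patches:
        name = f"{patch_set.slide_id}_r{patch.row}_c{patch.col}.png"
        Image.fromarray(patch.pixels, mode="RGB").save(out_dir / name)
        rows.append(
            {
                "slide_id": patch_set.slide_id,
                "patient_id": patch_set.patient_id,
                "row": patch.row,
                "col": patch.col,
                "foreground_fraction": patch.foreground_fraction,
                "label": patch_set.label,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["slide_id", "patient_id", "row", "col", "foreground_fraction", "label"]
    )
    manifest.to_csv(out_dir / f"{patch_set.slide_id}_patches.csv", index=False)
    return manifest
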