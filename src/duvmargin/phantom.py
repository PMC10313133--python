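"""Synthetic DUV-like phantom slides with per-patch ground truth.

A phantom slide is a near-black background (luma < 5) carrying elliptical
tissue regions: benign tissue in light/dark green hues, malignant tissue in
pink/yellow hues with a higher density of bright "nuclei" spots.  Every slide
comes with a pixel-level tissue mask and grid-level ground-truth patch
labels, so the full pipeline can run and be scored without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from duvmargin.tiling import SlideRecord, plan_grid

__all__ = [
    "Region",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSlide",
    "generate_slide",
    "generate_cohort",
    "write_cohort",
    "BENIGN_PALETTE",
    "MALIGNANT_PALETTE",
]

MALIGNANT = 1
BENIGN = -1

BACKGROUND_CODE = 0
BENIGN_CODE = 1
MALIGNANT_CODE = 2

#: Benign tissue hues: light green and dark green.
BENIGN_PALETTE = ((110, 200, 110), (25, 115, 35))
#: Malignant tissue hues: pink and yellow.
MALIGNANT_PALETTE = ((235, 105, 170), (235, 215, 60))

#: Bright-spot ("nuclei") densities per pixel of tissue.
SPOT_DENSITY = {"benign": 4e-5, "malignant": 2.5e-4}


@dataclass(frozen=True)
class Region:
    """Elliptical or rectangular tissue region; later regions overwrite earlier.

    A rectangle spans the half-open box ``[cy - ry, cy + ry) x [cx - rx, cx + rx)``.
    """

    center: tuple[float, float]  # (y, x)
    radii: tuple[float, float]  # (ry, rx)
    tissue_class: str  # "benign" | "malignant"
    palette_index: int = 0
    shape: str = "ellipse"  # "ellipse" | "rect"

    def __post_init__(self) -> None:
        if self.tissue_class not in ("benign", "malignant"):
            raise ValueError(f"unknown tissue_class {self.tissue_class!r}")
        if self.shape not in ("ellipse", "rect"):
            raise ValueError(f"unknown region shape {self.shape!r}")
        if min(self.radii) <= 0:
            raise ValueError(f"degenerate region: radii must be positive, got {self.radii}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom slide; reproducible from ``seed``."""

    height: int = 1200
    width: int = 1600
    regions: tuple[Region, ...] = ()
    patch_size: int = 400
    noise_sd: float = 6.0
    spot_density: dict = field(default_factory=lambda: dict(SPOT_DENSITY))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        for region in self.regions:
            cy, cx = region.center
            if not (0 <= cy < self.height and 0 <= cx < self.width):
                raise ValueError(f"region center {region.center} outside slide bounds")


@dataclass
class PhantomTruth:
    """Ground truth for one phantom slide.

    ``mask`` codes pixels {0 background, 1 benign, 2 malignant};
    ``majority_grid`` holds the plurality class per patch cell (0 where
    background dominates); ``tissue_grid`` compares only tissue pixels
    (+1 malignant-heavy, -1 benign-heavy, 0 no tissue).
    """

    mask: np.ndarray
    majority_grid: np.ndarray
    tissue_grid: np.ndarray


@dataclass
class CohortSlide:
    slide: SlideRecord
    truth: PhantomTruth
    spec: PhantomSpec | None = None


def _region_mask(height: int, width: int, region: Region) -> np.ndarray:
    cy, cx = region.center
    ry, rx = region.radii
    ys = np.arange(height)[:, None]
    xs = np.arange(width)[None, :]
    if region.shape == "rect":
        return (ys >= cy - ry) & (ys < cy + ry) & (xs >= cx - rx) & (xs < cx + rx)
    return ((ys - cy) / ry) ** 2 + ((xs - cx) / rx) ** 2 <= 1.0


def _scatter_spots(
    image: np.ndarray, mask: np.ndarray, code: int, density: float, rng: np.random.Generator
) -> None:
    """Draw small bright discs on tissue pixels of the given class, in place."""
    candidates = np.flatnonzero(mask == code)
    if candidates.size == 0 or density <= 0:
        return
    n_spots = rng.poisson(density * candidates.size)
    if n_spots == 0:
        return
    picks = rng.choice(candidates, size=min(n_spots, candidates.size), replace=False)
    h, w = mask.shape
    ys, xs = np.unravel_index(picks, mask.shape)
    for y, x in zip(ys, xs):
        radius = int(rng.integers(2, 4))
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        x0, x1 = max(0, x - radius), min(w, x + radius + 1)
        yy, xx = np.ogrid[y0:y1, x0:x1]
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= radius**2
        block = image[y0:y1, x0:x1]
        block[disc] = np.clip(block[disc].astype(np.int16) + 60, 0, 255).astype(np.uint8)


def _grid_truth(mask: np.ndarray, patch_size: int) -> tuple[np.ndarray, np.ndarray]:
    plan = plan_grid(mask.shape[0], mask.shape[1], patch_size)
    if mask.shape != (plan.resized_h, plan.resized_w):
        resized = Image.fromarray(mask, mode="L").resize(
            (plan.resized_w, plan.resized_h), Image.NEAREST
        )
        mask = np.asarray(resized)
    p = patch_size
    majority = np.zeros((plan.rows, plan.cols), dtype=int)
    tissue = np.zeros((plan.rows, plan.cols), dtype=int)
    for r in range(plan.rows):
        for c in range(plan.cols):
            cell = mask[r * p : (r + 1) * p, c * p : (c + 1) * p]
            n_bg = int(np.sum(cell == BACKGROUND_CODE))
            n_ben = int(np.sum(cell == BENIGN_CODE))
            n_mal = int(np.sum(cell == MALIGNANT_CODE))
            # Plurality with tissue preferred on ties, malignant over benign.
            if n_mal >= n_ben and n_mal >= n_bg and n_mal > 0:
                majority[r, c] = MALIGNANT
            elif n_ben >= n_bg and n_ben > 0:
                majority[r, c] = BENIGN
            else:
                majority[r, c] = 0
            if n_mal + n_ben > 0:
                tissue[r, c] = MALIGNANT if n_mal > n_ben else BENIGN
    return majority, tissue


def generate_slide(
    spec: PhantomSpec, slide_id: str = "phantom", patient_id: str = "P0", label: int | None = None
) -> CohortSlide:
    """Render a phantom slide from its spec; bit-identical for a fixed seed.

    ``label`` defaults to +1 when any malignant region is present, else -1.
    """
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    image = rng.integers(0, 3, size=(spec.height, spec.width, 3)).astype(np.uint8)

    for region in spec.regions:
        footprint = _region_mask(spec.height, spec.width, region)
        if not footprint.any():
            raise ValueError(f"region {region} has zero area inside the slide")
        code = MALIGNANT_CODE if region.tissue_class == "malignant" else BENIGN_CODE
        palette = MALIGNANT_PALETTE if code == MALIGNANT_CODE else BENIGN_PALETTE
        color = palette[region.palette_index % len(palette)]
        mask[footprint] = code
        image[footprint] = color

    tissue = mask > 0
    if tissue.any() and spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=(int(tissue.sum()), 3))
        image[tissue] = np.clip(image[tissue].astype(np.float64) + noise, 0, 255).astype(np.uint8)
    _scatter_spots(image, mask, BENIGN_CODE, spec.spot_density.get("benign", 0.0), rng)
    _scatter_spots(image, mask, MALIGNANT_CODE, spec.spot_density.get("malignant", 0.0), rng)
    # Background luma must stay below the foreground threshold after noise.
    image[~tissue] = np.minimum(image[~tissue], 4)

    majority, tissue_grid = _grid_truth(mask, spec.patch_size)
    if label is None:
        label = MALIGNANT if any(r.tissue_class == "malignant" for r in spec.regions) else BENIGN
    slide = SlideRecord(slide_id=slide_id, patient_id=patient_id, pixels=image, label=label)
    return CohortSlide(
        slide=slide,
        truth=PhantomTruth(mask=mask, majority_grid=majority, tissue_grid=tissue_grid),
        spec=spec,
    )


def _random_slide_spec(
    label: int,
    height: int,
    width: int,
    patch_size: int,
    rng: np.random.Generator,
    aligned_foci: bool = False,
) -> PhantomSpec:
    """Random tissue layout: a large benign ellipse, plus malignant foci for
    malignant slides centered near patch centers so at least one grid cell is
    malignant-dominant."""
    cy = height / 2 + rng.uniform(-60, 60)
    cx = width / 2 + rng.uniform(-60, 60)
    ry = rng.uniform(0.40, 0.48) * height
    rx = rng.uniform(0.40, 0.48) * width
    regions = [
        Region(
            center=(cy, cx),
            radii=(ry, rx),
            tissue_class="benign",
            palette_index=int(rng.integers(0, 2)),
        )
    ]
    if label == MALIGNANT:
        plan = plan_grid(height, width, patch_size)
        centers = [
            ((r + 0.5) * patch_size, (c + 0.5) * patch_size)
            for r in range(plan.rows)
            for c in range(plan.cols)
        ]
        # Keep foci on patch centers well inside the benign ellipse.
        inside = [
            (y, x)
            for y, x in centers
            if ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 0.45
        ]
        if not inside:
            inside = [(cy, cx)]
        n_foci = int(rng.integers(1, 3))
        picks = rng.choice(len(inside), size=min(n_foci, len(inside)), replace=False)
        for pick in np.atleast_1d(picks):
            y, x = inside[int(pick)]
            if aligned_foci:
                # rectangle snapped to exactly one grid cell: pure patches
                shape, radii = "rect", (patch_size / 2, patch_size / 2)
            else:
                radius = rng.uniform(300, 420)
                shape, radii = "ellipse", (radius, radius)
            regions.append(
                Region(
                    center=(float(y), float(x)),
                    radii=radii,
                    tissue_class="malignant",
                    palette_index=int(rng.integers(0, 2)),
                    shape=shape,
                )
            )
    return PhantomSpec(
        height=height,
        width=width,
        regions=tuple(regions),
        patch_size=patch_size,
        seed=int(rng.integers(0, 2**31)),
    )


def generate_cohort(
    n_benign: int = 24,
    n_malignant: int = 36,
    seed: int = 0,
    height: int = 1200,
    width: int = 1600,
    patch_size: int = 400,
    aligned_foci: bool = False,
) -> list[CohortSlide]:
    """Synthesize a slide cohort mirroring the 24 benign / 36 malignant default.

    Patient ids are mostly unique but every fourth patient contributes two
    slides, exercising grouped cross-validation.  ``aligned_foci`` snaps
    malignant foci to whole grid cells so every patch is class-pure.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("cohort counts must be non-negative")
    if n_benign + n_malignant == 0:
        raise ValueError("cohort must contain at least one slide")
    rng = np.random.default_rng(seed)
    slides: list[CohortSlide] = []
    index = 0
    for label, count, prefix in ((BENIGN, n_benign, "B"), (MALIGNANT, n_malignant, "M")):
        patient_no = 0
        slides_for_patient = 0
        for i in range(count):
            if slides_for_patient == 0:
                patient_no += 1
                # every 4th patient of a class has two slides
                slides_for_patient = 2 if patient_no % 4 == 0 else 1
            spec = _random_slide_spec(label, height, width, patch_size, rng, aligned_foci)
            slides.append(
                generate_slide(
                    spec,
                    slide_id=f"S{index:03d}",
                    patient_id=f"P{prefix}{patient_no:03d}",
                    label=label,
                )
            )
            slides_for_patient -= 1
            index += 1
    return slides


def write_cohort(slides: list[CohortSlide], out_dir: str | Path) -> pd.DataFrame:
    """Persist slides as PNG, masks as PNG, plus a cohort manifest CSV."""
    out_dir = Path(out_dir)
    (out_dir / "slides").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for item in slides:
        slide = item.slide
        Image.fromarray(slide.pixels, mode="RGB").save(out_dir / "slides" / f"{slide.slide_id}.png")
        Image.fromarray(item.truth.mask, mode="L").save(
            out_dir / "masks" / f"{slide.slide_id}_mask.png"
        )
        rows.append(
            {"slide_id": slide.slide_id, "patient_id": slide.patient_id, "label": slide.label}
        )
    manifest = pd.DataFrame(rows, columns=["slide_id", "patient_id", "label"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
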