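"""Importance-weighted fusion of patch labels into a slide-level decision.

Per valid patch j of slide i: the mean importance r_ij over the patch
footprint is thresholded into a weight w_ij (zero below 0.25), multiplied by
the patch label y_ij into u_ij, and the count H_i of strictly positive u_ij
is compared against q * M_i to call the slide.  A plain majority-vote
baseline is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FusionResult",
    "patch_importance",
    "patch_weight",
    "slide_decision",
    "majority_vote",
    "fuse_patch_set",
    "write_fusion_report",
    "IMPORTANCE_THRESHOLD",
]

MALIGNANT = 1
BENIGN = -1

#: Patches with mean importance below this value are ignored in the fusion.
IMPORTANCE_THRESHOLD = 0.25


@dataclass
class FusionResult:
    """Per-patch fusion terms and the slide-level call."""

    r: np.ndarray  # mean importance per patch, in [0, 1]
    w: np.ndarray  # thresholded weights, {0} U [threshold, 1]
    u: np.ndarray  # w * y
    labels: np.ndarray  # patch labels y_ij
    h: int  # count of u > 0 (weighted malignant patches)
    m: int  # valid patch count M_i
    q: float
    slide_label: int  # y_i in {+1, -1}
    rows: np.ndarray | None = None  # optional grid bookkeeping
    cols: np.ndarray | None = None


def patch_importance(map_values: np.ndarray, row: int, col: int, patch_size: int) -> float:
    """Mean importance over the (row, col) patch footprint of the map."""
    map_values = np.asarray(map_values)
    top, left = row * patch_size, col * patch_size
    if row < 0 or col < 0:
        raise ValueError(f"patch indices must be non-negative, got ({row}, {col})")
    if top + patch_size > map_values.shape[0] or left + patch_size > map_values.shape[1]:
        raise ValueError(
            f"patch ({row}, {col}) footprint exceeds map shape {map_values.shape}"
        )
    return float(map_values[top : top + patch_size, left : left + patch_size].mean())


def patch_weight(r: float, threshold: float = IMPORTANCE_THRESHOLD) -> float:
    """0 when r < threshold, else r itself (boundary value is kept)."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"importance must lie in [0, 1], got {r}")
    return 0.0 if r < threshold else float(r)


def slide_decision(labels, weights, q: float = 0.0) -> FusionResult:
    """Fuse patch labels and weights into the slide label.

    ``u_ij = w_ij * y_ij``; ``H_i`` counts strictly positive ``u_ij``; the
    slide is malignant (+1) iff ``H_i > q * M_i``.
    """
    labels = np.asarray(labels, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("slide has no valid patches; cannot fuse an empty list")
    if labels.shape != weights.shape:
        raise ValueError("labels and weights must have equal length")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if not np.all(np.isin(labels, (MALIGNANT, BENIGN))):
        raise ValueError("patch labels must be +1/-1")

    u = weights * labels
    h = int(np.sum(u > 0))
    m = int(labels.size)
    slide_label = MALIGNANT if h > q * m else BENIGN
    return FusionResult(
        r=weights.copy(),
        w=weights,
        u=u,
        labels=labels.astype(int),
        h=h,
        m=m,
        q=float(q),
        slide_label=slide_label,
    )


def majority_vote(labels) -> int:
    """+1 when malignant patches outnumber benign ones; ties go malignant."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("majority vote over an empty label list")
    if not np.all(np.isin(labels, (MALIGNANT, BENIGN))):
        raise ValueError("patch labels must be +1/-1")
    pos = int(np.sum(labels == MALIGNANT))
    neg = int(labels.size - pos)
    return MALIGNANT if pos >= neg else BENIGN


def fuse_patch_set(
    patch_rows,
    patch_cols,
    patch_labels,
    map_values: np.ndarray,
    patch_size: int,
    q: float = 0.0,
    threshold: float = IMPORTANCE_THRESHOLD,
) -> FusionResult:
    """Compute r/w/u for every valid patch of a slide and fuse the decision."""
    rows = np.asarray(patch_rows, dtype=int)
    cols = np.asarray(patch_cols, dtype=int)
    labels = np.asarray(patch_labels, dtype=int)
    if not (rows.shape == cols.shape == labels.shape):
        raise ValueError("rows, cols and labels must align")
    r = np.array(
        [patch_importance(map_values, ri, ci, patch_size) for ri, ci in zip(rows, cols)]
    )
    w = np.array([patch_weight(val, threshold) for val in r])
    result = slide_decision(labels, w, q)
    result.r = r
    result.rows = rows
    result.cols = cols
    return result


def write_fusion_report(results: dict[str, FusionResult], path: str | Path) -> pd.DataFrame:
    """Per-patch fusion report CSV across slides (one row per valid patch)."""
    records = []
    for slide_id, res in results.items():
        rows = res.rows if res.rows is not None else np.full(res.m, -1)
        cols = res.cols if res.cols is not None else np.full(res.m, -1)
        for j in range(res.m):
            records.append(
                {
                    "slide_id": slide_id,
                    "M": res.m,
                    "H": res.h,
                    "q": res.q,
                    "slide_label": res.slide_label,
                    "row": int(rows[j]),
                    "col": int(cols[j]),
                    "patch_label": int(res.labels[j]),
                    "r": float(res.r[j]),
                    "w": float(res.w[j]),
                    "u": float(res.u[j]),
                }
            )
    report = pd.DataFrame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(path, index=False)
    return report
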