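"""Segmentation evaluation: IoU, DSC, ASSD, 26-connectivity components, reports.

IoU(X, Y) = |X ∩ Y| / |X ∪ Y| and DSC(X, Y) = 2|X ∩ Y| / (|X| + |Y|) are
computed by voxel counting; the algebraic identity DSC = 2·IoU/(1 + IoU)
holds exactly. ASSD is the average symmetric surface distance in mm: the mean
of all minimum Euclidean distances from boundary voxels of one mask to the
boundary of the other, in both directions. Boundaries use face (6-neighbor)
adjacency with the volume border counting as background, the conventional
surface definition for surface-distance metrics; connected components use
the full 26-neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError, ShapeError, UndefinedMeasureError
from .volumes import BinaryMask

__all__ = [
    "MetricsReport",
    "iou",
    "dsc",
    "assd",
    "connected_components_26",
    "refine_segmentation",
    "evaluate",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if data.ndim != 3:
        raise ShapeError(f"mask must be rank 3, got rank {data.ndim}")
    return data.astype(bool)


def _check_pair(X, Y) -> tuple[np.ndarray, np.ndarray]:
    x, y = _as_bool(X), _as_bool(Y)
    if x.shape != y.shape:
        raise ShapeError(f"mask shapes differ: {x.shape} vs {y.shape}")
    return x, y


def iou(X, Y) -> float:
    """Jaccard index |X ∩ Y| / |X ∪ Y| by voxel counting."""
    x, y = _check_pair(X, Y)
    union = np.count_nonzero(x | y)
    if union == 0:
        raise UndefinedMeasureError("IoU undefined: both masks are empty")
    return np.count_nonzero(x & y) / union


def dsc(X, Y) -> float:
    """Dice similarity coefficient 2|X ∩ Y| / (|X| + |Y|)."""
    x, y = _check_pair(X, Y)
    denom = np.count_nonzero(x) + np.count_nonzero(y)
    if denom == 0:
        raise UndefinedMeasureError("DSC undefined: both masks are empty")
    return 2.0 * np.count_nonzero(x & y) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 background 6-neighbor (border = background)."""
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT_6, border_value=0)
    return mask & ~eroded


def assd(X, Y, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm.

    Mean over both directions of the minimum Euclidean distance (scaled by
    voxel spacing) from each boundary voxel of one mask to the boundary voxel
    set of the other.
    """
    x, y = _check_pair(X, Y)
    if isinstance(X, BinaryMask) and isinstance(Y, BinaryMask) and X.spacing != Y.spacing:
        raise InputError(f"mask spacings differ: {X.spacing} vs {Y.spacing}")
    if isinstance(X, BinaryMask):
        spacing = X.spacing
    if not x.any() or not y.any():
        raise UndefinedMeasureError("ASSD undefined: a mask is empty")
    bx, by = _boundary(x), _boundary(y)
    # exact Euclidean distance to the nearest boundary voxel of the other mask
    d_to_y = ndimage.distance_transform_edt(~by, sampling=spacing)
    d_to_x = ndimage.distance_transform_edt(~bx, sampling=spacing)
    total = d_to_y[bx].sum() + d_to_x[by].sum()
    return float(total / (np.count_nonzero(bx) + np.count_nonzero(by)))


def connected_components_26(mask) -> tuple[np.ndarray, int]:
    """Label maximal 26-connected foreground components.

    Labels are positive integers assigned in first-encounter raster order;
    background is 0. An empty mask yields count 0.
    """
    m = _as_bool(mask)
    labels, n = ndimage.label(m, structure=_STRUCT_26)
    if n > 1:
        # renumber so label k is the k-th component met in raster scan order
        first_seen = pd.unique(labels.ravel())
        first_seen = first_seen[first_seen != 0]
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[first_seen] = np.arange(1, n + 1)
        labels = remap[labels]
    return labels, int(n)


def refine_segmentation(mask, min_size: int = 0) -> BinaryMask:
    """Drop 26-connected components smaller than ``min_size`` voxels.

    ``min_size = 0`` is the identity. This is the full-volume postprocessing
    step applied to stitched predictions.
    """
    m = _as_bool(mask)
    spacing = mask.spacing if isinstance(mask, BinaryMask) else (1.0, 1.0, 1.0)
    if min_size > 0 and m.any():
        labels, n = connected_components_26(m)
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep = sizes >= min_size
        keep[0] = False
        m = keep[labels]
    return BinaryMask(data=m.astype(np.uint8), spacing=spacing)


@dataclass
class MetricsReport:
    """Per-subject IoU/DSC/ASSD rows plus mean and sample-std summaries."""

    per_subject: pd.DataFrame  # columns: subject_id, iou, dsc, assd_mm, defined
    summary: dict

    def to_csv(self, path) -> None:
        self.per_subject.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {
            "per_subject": self.per_subject.to_dict(orient="records"),
            "summary": self.summary,
        }


def evaluate(predictions, truths, subject_ids) -> MetricsReport:
    """Per-subject IoU/DSC/ASSD with mean and sample (n-1) standard deviation.

    Subjects for which a measure is undefined (e.g. both masks empty, or an
    empty mask for ASSD) are flagged, excluded from the summaries, and
    counted in ``summary["n_undefined"]``.
    """
    predictions, truths, subject_ids = list(predictions), list(truths), list(subject_ids)
    if not (len(predictions) == len(truths) == len(subject_ids)):
        raise InputError(
            f"length mismatch: {len(predictions)} predictions, {len(truths)} truths, "
            f"{len(subject_ids)} subject IDs"
        )
    rows = []
    for pred, truth, sid in zip(predictions, truths, subject_ids):
        row = {"subject_id": sid, "iou": np.nan, "dsc": np.nan, "assd_mm": np.nan, "defined": True}
        try:
            row["iou"] = iou(pred, truth)
            row["dsc"] = dsc(pred, truth)
        except UndefinedMeasureError:
            row["defined"] = False
        try:
            row["assd_mm"] = assd(pred, truth)
        except UndefinedMeasureError:
            row["defined"] = False
        rows.append(row)
    table = pd.DataFrame(rows, columns=["subject_id", "iou", "dsc", "assd_mm", "defined"])
    ok = table[table["defined"]]
    summary = {"n_subjects": len(table), "n_undefined": int((~table["defined"]).sum())}
    for measure in ("iou", "dsc", "assd_mm"):
        vals = ok[measure].to_numpy(dtype=float)
        summary[f"{measure}_mean"] = float(np.mean(vals)) if vals.size else float("nan")
        summary[f"{measure}_std"] = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return MetricsReport(per_subject=table, summary=summary)
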