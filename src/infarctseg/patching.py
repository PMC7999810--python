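"""Overlapped-patches strategy: pad, tile, prune, reference IDs, stitch.

A volume is zero-padded at the trailing end of each axis to the next multiple
of the patch edge (so a 197x233x189 scan becomes 256x256x192), then tiled
into cubic patches. In "grid" mode origins step by the full patch edge
(a 256x256x192 volume yields 4*4*3 = 48 patches); in "overlap" mode origins
step by ``patch_size - overlap`` with the last origin clamped flush to the
padded boundary. Patches whose voxel sum is zero can be pruned before
segmentation; their reference IDs are recorded so stitching can re-substitute
zeros and every subject keeps the same patch geometry.

Reference IDs are "<subject_id>_patch_<serial>" with serials 1-based in
origin-lexicographic order (axis 0 slowest), e.g. "c0003_patch_1".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConsistencyError, InputError, ParameterError, ValidationError

__all__ = [
    "PatchGrid",
    "PatchSet",
    "pad_volume",
    "divide_patches",
    "make_reference_id",
    "parse_reference_id",
    "stitch_patches",
    "save_patchset",
    "load_patchset",
]

_REF_TOKEN = "_patch_"


@dataclass
class PatchGrid:
    """Tiling geometry of one volume."""

    original_shape: tuple[int, int, int]
    padded_shape: tuple[int, int, int]
    patch_size: int
    overlap: int
    origins: list[tuple[int, int, int]]
    mode: str  # "grid" | "overlap"

    def __post_init__(self):
        for orig, pad in zip(self.original_shape, self.padded_shape):
            if pad < orig:
                raise ValidationError("padded dimension smaller than original")
        for o in self.origins:
            if any(oi + self.patch_size > pi for oi, pi in zip(o, self.padded_shape)):
                raise ValidationError(f"origin {o} overruns padded shape {self.padded_shape}")
        if self.origins != sorted(self.origins):
            raise ValidationError("origins must be lexicographically ordered")

    @property
    def n_patches(self) -> int:
        return len(self.origins)


@dataclass
class PatchSet:
    """Retained patches plus pruning records for one subject."""

    grid: PatchGrid
    patches: list[tuple[str, np.ndarray]]
    pruned_ids: list[str]
    subject_id: str = ""

    def __post_init__(self):
        ids = [rid for rid, _ in self.patches] + list(self.pruned_ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate reference IDs")
        if len(ids) != self.grid.n_patches:
            raise ValidationError(
                f"{len(ids)} reference IDs for {self.grid.n_patches} grid origins"
            )
        p = self.grid.patch_size
        for rid, patch in self.patches:
            if patch.shape != (p, p, p):
                raise ValidationError(f"{rid}: patch shape {patch.shape} != {(p, p, p)}")

    @property
    def reference_ids(self) -> list[str]:
        return [rid for rid, _ in self.patches]


def make_reference_id(subject_id: str, serial: int) -> str:
    """``("c0003", 1) -> "c0003_patch_1"``; inverted exactly by :func:`parse_reference_id`."""
    if serial < 1:
        raise ValidationError(f"serial must be >= 1, got {serial}")
    if _REF_TOKEN in subject_id:
        raise ValidationError(
            f"subject_id {subject_id!r} contains {_REF_TOKEN!r}; reference IDs would be ambiguous"
        )
    return f"{subject_id}{_REF_TOKEN}{serial}"


def parse_reference_id(reference_id: str) -> tuple[str, int]:
    subject_id, sep, serial = reference_id.rpartition(_REF_TOKEN)
    if not sep or not serial.isdigit() or int(serial) < 1:
        raise ValidationError(f"not a valid reference ID: {reference_id!r}")
    return subject_id, int(serial)


def pad_volume(volume: np.ndarray, patch_size: int) -> tuple[np.ndarray, PatchGrid]:
    """Zero-pad each axis at the trailing end to the next multiple of ``patch_size``.

    Original content stays at the leading corner. Returns the padded array and
    a PatchGrid stub (grid mode, no overlap).
    """
    if patch_size < 1:
        raise ParameterError(f"patch_size must be >= 1, got {patch_size}")
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise InputError(f"expected rank-3 volume, got rank {volume.ndim}")
    original = volume.shape
    padded_shape = tuple(-(-d // patch_size) * patch_size for d in original)
    if padded_shape != original:
        pad = [(0, p - d) for d, p in zip(original, padded_shape)]
        volume = np.pad(volume, pad, mode="constant")
    grid = PatchGrid(
        original_shape=tuple(original),
        padded_shape=padded_shape,
        patch_size=patch_size,
        overlap=0,
        origins=_grid_origins(padded_shape, patch_size, 0, "grid"),
        mode="grid",
    )
    return volume, grid


def _axis_origins(dim: int, patch_size: int, stride: int) -> list[int]:
    starts = list(range(0, dim - patch_size + 1, stride))
    if starts[-1] != dim - patch_size:  # clamp flush with the boundary
        starts.append(dim - patch_size)
    return starts


def _grid_origins(padded_shape, patch_size: int, overlap: int, mode: str):
    stride = patch_size if mode == "grid" else patch_size - overlap
    per_axis = [_axis_origins(d, patch_size, stride) for d in padded_shape]
    return [
        (a, b, c) for a in per_axis[0] for b in per_axis[1] for c in per_axis[2]
    ]


def divide_patches(
    volume: np.ndarray,
    subject_id: str,
    patch_size: int = 64,
    overlap: int = 10,
    mode: str = "grid",
    prune: bool = True,
) -> PatchSet:
    """Pad and tile a volume into cubic patches with reference IDs.

    In grid mode, origins step by ``patch_size`` (count = prod(ceil(dim/p)));
    in overlap mode they step by ``patch_size - overlap`` with the final
    origin per axis clamped flush to the padded boundary. With ``prune=True``,
    patches whose voxel sum equals zero are moved to ``pruned_ids``.
    """
    if mode not in ("grid", "overlap"):
        raise ParameterError(f"unknown mode: {mode!r}")
    if mode == "overlap" and not (0 <= overlap < patch_size):
        raise ParameterError(f"overlap must satisfy 0 <= overlap < patch_size, got {overlap}")
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise InputError("volume contains non-finite values")
    padded, stub = pad_volume(volume, patch_size)
    origins = _grid_origins(stub.padded_shape, patch_size, overlap, mode)
    grid = PatchGrid(
        original_shape=stub.original_shape,
        padded_shape=stub.padded_shape,
        patch_size=patch_size,
        overlap=overlap if mode == "overlap" else 0,
        origins=origins,
        mode=mode,
    )
    patches: list[tuple[str, np.ndarray]] = []
    pruned: list[str] = []
    p = patch_size
    for serial, (a, b, c) in enumerate(origins, start=1):
        rid = make_reference_id(subject_id, serial)
        block = padded[a : a + p, b : b + p, c : c + p]
        if prune and block.sum() == 0:
            pruned.append(rid)
        else:
            patches.append((rid, block.copy()))
    return PatchSet(grid=grid, patches=patches, pruned_ids=pruned, subject_id=subject_id)


def stitch_patches(
    patch_predictions: list[tuple[str, np.ndarray]],
    grid: PatchGrid,
    combine: str = "mean",
) -> np.ndarray:
    """Reassemble patch outputs to a full volume of ``grid.original_shape``.

    Missing reference IDs are treated as pruned: their voxels are zero. Where
    overlap-mode patches cover a voxel more than once, contributions are
    combined by ``combine``: "mean" averages (probabilities) and "vote" takes
    the strict majority of binary labels (ties go to background).
    """
    if combine not in ("mean", "vote"):
        raise ParameterError(f"unknown combine rule: {combine!r}")
    p = grid.patch_size
    acc = np.zeros(grid.padded_shape, dtype=np.float64)
    cnt = np.zeros(grid.padded_shape, dtype=np.int32)
    origin_by_serial = {s: o for s, o in enumerate(grid.origins, start=1)}
    for rid, patch in patch_predictions:
        _, serial = parse_reference_id(rid)
        if serial not in origin_by_serial:
            raise ConsistencyError(f"reference ID {rid!r} has no origin in the grid")
        patch = np.asarray(patch)
        if patch.shape != (p, p, p):
            raise ConsistencyError(f"{rid}: patch shape {patch.shape} != {(p, p, p)}")
        a, b, c = origin_by_serial[serial]
        acc[a : a + p, b : b + p, c : c + p] += patch
        cnt[a : a + p, b : b + p, c : c + p] += 1
    covered = cnt > 0
    out = np.zeros(grid.padded_shape, dtype=np.float64)
    if combine == "mean":
        out[covered] = acc[covered] / cnt[covered]
    else:
        out[covered] = (2 * acc[covered] > cnt[covered]).astype(np.float64)
    s = tuple(slice(0, d) for d in grid.original_shape)
    return out[s]


def save_patchset(patchset: PatchSet, directory) -> None:
    """Persist a PatchSet as one NIfTI file per retained patch plus a JSON sidecar."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rid, patch in patchset.patches:
        img = nib.Nifti1Image(np.asarray(patch, dtype=np.float32), np.eye(4))
        nib.save(img, str(directory / f"{rid}.nii.gz"))
    sidecar = {
        "subject_id": patchset.subject_id,
        "pruned_ids": patchset.pruned_ids,
        "retained_ids": patchset.reference_ids,
        "grid": {
            "original_shape": list(patchset.grid.original_shape),
            "padded_shape": list(patchset.grid.padded_shape),
            "patch_size": patchset.grid.patch_size,
            "overlap": patchset.grid.overlap,
            "origins": [list(o) for o in patchset.grid.origins],
            "mode": patchset.grid.mode,
        },
    }
    (directory / "patchset.json").write_text(json.dumps(sidecar, indent=1))


def load_patchset(directory) -> PatchSet:
    import nibabel as nib

    directory = Path(directory)
    sidecar = json.loads((directory / "patchset.json").read_text())
    g = sidecar["grid"]
    grid = PatchGrid(
        original_shape=tuple(g["original_shape"]),
        padded_shape=tuple(g["padded_shape"]),
        patch_size=g["patch_size"],
        overlap=g["overlap"],
        origins=[tuple(o) for o in g["origins"]],
        mode=g["mode"],
    )
    patches = []
    for rid in sidecar["retained_ids"]:
        data = np.asanyarray(nib.load(str(directory / f"{rid}.nii.gz")).dataobj)
        patches.append((rid, np.asarray(data, dtype=np.float32)))
    return PatchSet(
        grid=grid,
        patches=patches,
        pruned_ids=list(sidecar["pruned_ids"]),
        subject_id=sidecar["subject_id"],
    )
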