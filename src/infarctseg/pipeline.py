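"""End-to-end orchestration: dataset split, preprocess, train, predict, evaluate.

The pipeline follows the study workflow: (1) split subjects 60/20/20 into
train/validation/test, (2) skull-strip and apply VMD-based candidate masking,
(3) divide volumes into patches with pruning and reference IDs, (4) train the
3D U-Net on training patches with validation monitoring, (5) segment test
patches and stitch them back (zeros re-substituted for pruned patches),
(6) refine with 26-connectivity component filtering and evaluate IoU/DSC/ASSD
against ground truth. A run is fully reproducible from its config + seed.
"""

from __future__ import annotations

import json
import math
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import InputError, ParameterError, StageError
from .metrics import MetricsReport, evaluate, refine_segmentation
from .patching import divide_patches, stitch_patches
from .phantom import PhantomSpec, generate_cohort
from .unet3d import UNetConfig, build_unet3d, predict_patches, save_model, train
from .vmd import ThresholdPolicy, VMDParams, apply_mask, candidate_mask, vmd_volume
from .volumes import BinaryMask, VolumeImage, read_mask, read_volume, skull_strip, write_mask

__all__ = ["SplitSpec", "split_dataset", "PipelineConfig", "run_pipeline"]


@dataclass
class SplitSpec:
    """Train/validation/test split: ratios summing to 1 and an ordering rule."""

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    ordering: str = "sequential"  # or "seeded-shuffle"
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.ratios):
            raise ParameterError(f"ratios must be non-negative, got {self.ratios}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ParameterError(f"ratios must sum to 1, got {self.ratios}")
        if self.ordering not in ("sequential", "seeded-shuffle"):
            raise ParameterError(f"unknown ordering: {self.ordering!r}")


def split_dataset(subject_ids, spec: SplitSpec | None = None):
    """Partition subject IDs into (train, val, test) — disjoint and exhaustive.

    Sequential ordering sorts IDs lexicographically. Sizes: floor(n * r_train)
    for training, then the remainder is split val-first with round-half-up,
    test absorbing the residue — 239 subjects at 60/20/20 give (143, 48, 48).
    """
    spec = spec or SplitSpec()
    ids = list(subject_ids)
    if not ids:
        raise InputError("subject ID list is empty")
    if len(set(ids)) != len(ids):
        raise InputError("subject IDs must be unique")
    if spec.ordering == "sequential":
        ids = sorted(ids)
    else:
        rng = np.random.default_rng(spec.seed)
        ids = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    r_train, r_val, r_test = spec.ratios
    n_train = math.floor(n * r_train)
    rest = n - n_train
    if r_val + r_test > 0:
        n_val = math.floor(rest * r_val / (r_val + r_test) + 0.5)
    else:
        n_val = 0
    n_val = min(n_val, rest)
    return ids[:n_train], ids[n_train : n_train + n_val], ids[n_train + n_val :]


_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "run_output",
    "data": {
        # source "phantom" generates a synthetic cohort; "nifti" reads
        # volumes_dir/masks_dir with matching filenames
        "source": "phantom",
        "n_subjects": 10,
        "phantom": {},  # PhantomSpec overrides (shape, intensities, ...)
        "volumes_dir": None,
        "masks_dir": None,
    },
    "split": {"ratios": [0.6, 0.2, 0.2], "ordering": "sequential"},
    "skullstrip": {"backend": "morphological"},
    "vmd": {
        "enabled": True,
        "alpha": 1000.0,
        "K": 5,
        "tau": 0.5,
        "tol": None,
        "omega_init": "uniform",
        "max_iters": 500,
        "slice_axis": 2,
        "mode_index": 3,  # 1-based: the mode used for candidate masking
        "threshold_percentile": 75.0,
        "envelope_window": 5,
        "min_component_size": 27,
    },
    "patch": {"patch_size": 64, "overlap": 10, "mode": "grid", "prune": True},
    "unet": {},  # UNetConfig overrides
    "postprocess": {"min_component_size": 0, "combine": "vote"},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if key not in base:
            raise ParameterError(f"unknown config key: {key!r}")
        # empty-dict defaults (phantom/unet overrides) are free-form passthroughs
        if isinstance(base[key], dict) and isinstance(val, dict) and base[key]:
            out[key] = _deep_merge(base[key], val)
        else:
            out[key] = val
    return out


@dataclass
class PipelineConfig:
    """Declarative run configuration (see ``PipelineConfig.defaults()``)."""

    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.settings = _deep_merge(_DEFAULTS, self.settings)

    @staticmethod
    def defaults() -> dict:
        return json.loads(json.dumps(_DEFAULTS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.settings[key]


def _load_subjects(cfg: PipelineConfig) -> list[tuple[VolumeImage, BinaryMask]]:
    data = cfg["data"]
    if data["source"] == "phantom":
        template = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in data["phantom"].items()})
        return generate_cohort(int(data["n_subjects"]), template, seed=cfg["seed"])
    if data["source"] == "nifti":
        vol_dir, mask_dir = Path(data["volumes_dir"]), Path(data["masks_dir"])
        pairs = []
        for vol_path in sorted(vol_dir.glob("*.nii*")):
            mask_path = mask_dir / vol_path.name
            if not mask_path.exists():
                raise InputError(f"no mask for {vol_path.name} in {mask_dir}")
            pairs.append((read_volume(vol_path), read_mask(mask_path)))
        if not pairs:
            raise InputError(f"no NIfTI volumes found in {vol_dir}")
        return pairs
    raise ParameterError(f"unknown data source: {data['source']!r}")


def _preprocess_subject(volume: VolumeImage, cfg: PipelineConfig) -> VolumeImage:
    """Skull strip, VMD candidate masking, and intensity scaling to [0, 1]."""
    stripped = skull_strip(volume, backend=cfg["skullstrip"]["backend"])
    v = cfg["vmd"]
    if v["enabled"]:
        params = VMDParams(
            alpha=v["alpha"], K=v["K"], tau=v["tau"], tol=v["tol"],
            omega_init=v["omega_init"], max_iters=v["max_iters"],
        )
        modes = vmd_volume(stripped, params, slice_axis=v["slice_axis"])
        policy = ThresholdPolicy(
            percentile=v["threshold_percentile"],
            window=v["envelope_window"],
            min_component_size=v["min_component_size"],
        )
        mask = candidate_mask(modes[v["mode_index"] - 1], policy)
        out = apply_mask(stripped, mask)
    else:
        out = stripped
    peak = float(out.data.max())
    if peak > 0:
        out = out.with_data((out.data / peak).astype(np.float32))
    return out


def _patch_pairs(subjects, preprocessed, ids, cfg: PipelineConfig):
    p = cfg["patch"]
    pairs = []
    by_id = {vol.subject_id: (vol, msk) for vol, msk in subjects}
    pre_by_id = {vol.subject_id: vol for vol in preprocessed}
    for sid in ids:
        _, truth = by_id[sid]
        pre = pre_by_id[sid]
        img_set = divide_patches(
            pre.data, sid, patch_size=p["patch_size"], overlap=p["overlap"],
            mode=p["mode"], prune=p["prune"],
        )
        mask_set = divide_patches(
            truth.data, sid, patch_size=p["patch_size"], overlap=p["overlap"],
            mode=p["mode"], prune=False,
        )
        pairs.append((img_set, mask_set))
    return pairs


def run_pipeline(config) -> MetricsReport:
    """Execute the full segmentation workflow and write artifacts to disk.

    ``config`` may be a :class:`PipelineConfig`, a plain dict of overrides, or
    a path to a YAML file. Writes predicted masks, the trained model, the
    metrics report (CSV + JSON) and a run log; returns the report.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = PipelineConfig(dict(config))

    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "config": cfg.settings,
        "versions": {
            "infarctseg": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "stages": {},
    }

    def stage(name, fn, subject_id=None):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            log["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_log(out_dir, log)
            raise StageError(name, subject_id, exc) from exc
        log["stages"][name] = {"status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        return result

    subjects = stage("load", lambda: _load_subjects(cfg))
    ids = [vol.subject_id for vol, _ in subjects]
    split_spec = SplitSpec(
        ratios=tuple(cfg["split"]["ratios"]), ordering=cfg["split"]["ordering"], seed=cfg["seed"]
    )
    train_ids, val_ids, test_ids = stage("split", lambda: split_dataset(ids, split_spec))
    log["split"] = {"train": train_ids, "val": val_ids, "test": test_ids}

    def preprocess_all():
        out = []
        for vol, _ in subjects:
            try:
                out.append(_preprocess_subject(vol, cfg))
            except Exception as exc:
                raise StageError("preprocess", vol.subject_id, exc) from exc
        return out

    preprocessed = stage("preprocess", preprocess_all)

    train_pairs = _patch_pairs(subjects, preprocessed, train_ids, cfg)
    val_pairs = _patch_pairs(subjects, preprocessed, val_ids, cfg)
    test_sets = {
        sid: pair[0] for sid, pair in zip(test_ids, _patch_pairs(subjects, preprocessed, test_ids, cfg))
    }

    unet_overrides = dict(cfg["unet"])
    unet_overrides.setdefault("seed", cfg["seed"])
    unet_overrides.setdefault("patch_size", cfg["patch"]["patch_size"])
    unet_cfg = UNetConfig(**unet_overrides)
    model = stage("build", lambda: build_unet3d(unet_cfg))
    model = stage("train", lambda: train(model, train_pairs, val_pairs, unet_cfg))
    save_model(model, out_dir / "model")
    _write_history(out_dir, model.history)

    by_id = {vol.subject_id: (vol, msk) for vol, msk in subjects}
    post = cfg["postprocess"]
    predictions, truths = [], []
    pred_dir = out_dir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    for sid in test_ids:
        patch_set = test_sets[sid]

        def segment(sid=sid, patch_set=patch_set):
            labels = predict_patches(model, patch_set)
            stitched = stitch_patches(labels, patch_set.grid, combine=post["combine"])
            mask = BinaryMask(
                data=(stitched > 0.5).astype(np.uint8), spacing=by_id[sid][0].spacing
            )
            return refine_segmentation(mask, min_size=post["min_component_size"])

        pred = stage(f"predict:{sid}", segment, subject_id=sid)
        write_mask(pred, pred_dir / f"{sid}.nii.gz")
        predictions.append(pred)
        truths.append(by_id[sid][1])

    report = stage("evaluate", lambda: evaluate(predictions, truths, test_ids))
    report.to_csv(out_dir / "metrics.csv")
    (out_dir / "metrics.json").write_text(json.dumps(report.to_json(), indent=1, sort_keys=True))
    _write_log(out_dir, log)
    return report


def _write_history(out_dir: Path, history: list[dict]) -> None:
    lines = ["epoch,train_loss,val_loss"]
    lines += [f"{h['epoch']},{h['train_loss']},{h['val_loss']}" for h in history]
    (out_dir / "training_log.csv").write_text("\n".join(lines) + "\n")


def _write_log(out_dir: Path, log: dict) -> None:
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
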