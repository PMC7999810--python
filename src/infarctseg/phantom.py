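"""Synthetic T1-like brain phantoms with ground-truth lesion masks.

A phantom is a bright, centered "brain" ellipsoid with smooth low-frequency
texture, containing one or more darker ellipsoidal "infarct" lesions
(chronic infarcts are hypointense on T1), plus additive Gaussian noise
clipped at zero. Every stage of the pipeline — skull stripping, VMD
preprocessing, patching, training, evaluation — is exercisable on phantoms
without downloading a real dataset. Generation is fully reproducible from
the seed.

A cohort mimics the real study population: every subject has at least one
lesion and the majority have exactly one (about 58% of stroke subjects in
the reference dataset are single-lesion). Subject IDs follow the
"c0003s0004t01" cohort/subject/timepoint style.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import PlacementError, ValidationError
from .volumes import BinaryMask, VolumeImage

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "FULL_SIZE_SHAPE"]

# the standardized full-scan geometry (1 mm isotropic); handy for patch-count checks
FULL_SIZE_SHAPE = (197, 233, 189)


@dataclass
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic subject.

    Intensities are arbitrary units with ``lesion_intensity`` strictly below
    ``brain_intensity`` (infarcts are hypointense on T1). Lesion semi-axes
    are drawn uniformly from ``lesion_axes_range`` and lesions are placed
    fully inside the brain ellipsoid without mutual overlap.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    n_lesions: int = 1
    brain_axes: tuple[float, float, float] | None = None  # default: 0.42 * shape
    lesion_axes_range: tuple[float, float] = (4.0, 9.0)
    brain_intensity: float = 100.0
    lesion_intensity: float = 30.0
    noise_sd: float = 5.0
    texture_amplitude: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lesions < 0:
            raise ValidationError("n_lesions must be >= 0")
        if self.lesion_intensity >= self.brain_intensity:
            raise ValidationError("lesion_intensity must be < brain_intensity (hypointense on T1)")
        if self.brain_axes is None:
            self.brain_axes = tuple(0.42 * s for s in self.shape)
        lo, hi = self.lesion_axes_range
        if not (0 < lo <= hi):
            raise ValidationError(f"invalid lesion_axes_range {self.lesion_axes_range}")


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, BinaryMask]:
    """Generate one (volume, truth-mask) pair deterministically from ``spec.seed``.

    Lesion centers are rejection-sampled until each candidate ellipsoid lies
    fully inside the brain and clear of previously placed lesions; exhausting
    the retry budget raises :class:`PlacementError`.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid_mask(shape, center, spec.brain_axes)

    volume = np.zeros(shape, dtype=np.float64)
    volume[brain] = spec.brain_intensity
    if spec.texture_amplitude > 0:
        # smooth low-frequency texture so the brain is not perfectly flat
        texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=8.0)
        scale = np.abs(texture).max() or 1.0
        volume[brain] += (spec.texture_amplitude * texture / scale)[brain]

    truth = np.zeros(shape, dtype=bool)
    grown_truth = np.zeros(shape, dtype=bool)  # truth dilated by 1: enforced gap
    placed: list[tuple[np.ndarray, np.ndarray]] = []  # (center, axes)
    max_tries = 200
    for lesion_idx in range(spec.n_lesions):
        for _ in range(max_tries):
            axes = rng.uniform(*spec.lesion_axes_range, size=3)
            # inside the brain ellipsoid with a safety margin for the lesion extent
            margin = axes.max() + 1.0
            half = np.array(spec.brain_axes) - margin
            if np.any(half <= 0):
                continue
            frac = rng.uniform(-1.0, 1.0, size=3) * 0.9
            cand = np.array(center) + frac * half
            if (((cand - center) / half) ** 2).sum() > 1.0:
                continue
            lesion = _ellipsoid_mask(shape, cand, axes)
            if (lesion & grown_truth).any():  # voxel-exact disjointness
                continue
            volume[lesion] = spec.lesion_intensity
            truth |= lesion
            grown_truth |= ndimage.binary_dilation(lesion)
            placed.append((cand, axes))
            break
        else:
            raise PlacementError(
                f"could not place lesion {lesion_idx + 1}/{spec.n_lesions} "
                f"after {max_tries} attempts (brain too small for the lesion size range?)"
            )

    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, size=shape)
    volume = np.clip(volume, 0.0, None).astype(np.float32)

    subject_id = _subject_id(0)
    vol = VolumeImage(data=volume, spacing=(1.0, 1.0, 1.0), subject_id=subject_id)
    msk = BinaryMask(data=truth.astype(np.uint8), spacing=(1.0, 1.0, 1.0), subject_id=subject_id)
    # expose placed geometry for validation against analytic ellipsoid volumes
    msk.lesion_geometry = [(tuple(c), tuple(a)) for c, a in placed]
    return vol, msk


def _subject_id(index: int) -> str:
    # "c0003s0004t01"-style: cohort block of 25 subjects, 1-based numbering
    cohort = 3 + index // 25
    subject = 1 + index % 25
    return f"c{cohort:04d}s{subject:04d}t01"


def generate_cohort(
    n_subjects: int, template: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[VolumeImage, BinaryMask]]:
    """Generate a reproducible cohort of phantom subjects with distinct IDs.

    Per-subject seeds are spawned deterministically from ``seed``. Lesion
    counts vary with a single-lesion majority (P(1)=0.6, P(2)=0.3, P(3)=0.1),
    so every subject has at least one lesion.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    template = template or PhantomSpec()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        volume = mask = None
        # a crowded draw (e.g. three large lesions in a small brain) is
        # redrawn deterministically rather than failing the whole cohort
        for _ in range(20):
            spec = replace(
                template,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
                n_lesions=int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])),
            )
            try:
                volume, mask = generate_phantom(spec)
                break
            except PlacementError:
                continue
        if volume is None:
            raise PlacementError(
                f"subject {i}: no feasible lesion layout in 20 redraws "
                f"(lesion size range too large for the phantom shape?)"
            )
        sid = _subject_id(i)
        volume.subject_id = sid
        mask.subject_id = sid
        cohort.append((volume, mask))
    return cohort
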