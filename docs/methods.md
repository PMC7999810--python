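# Methods

`infarctseg` implements an automated pipeline for segmenting chronic infarct
(stroke) lesions in T1-weighted brain MRI. On T1 scans chronic infarcts are
hypointense: darker than surrounding parenchyma, with shapes and sizes that
vary enormously across patients. The pipeline combines a spectral
preprocessing step (variational mode decomposition) that suppresses tissue
unlikely to be lesion, a volumetric patch strategy that keeps the
segmentation network small, a 3D U-Net that labels each patch voxel-wise, and
a connected-component postprocessing and evaluation stage.

## Pipeline model

For a cohort of scans S with manual lesion masks M the workflow is:

1. **Split.** Subjects are partitioned 60/20/20 into train/validation/test.
   The sequential rule sorts IDs lexicographically, assigns
   `floor(0.6 n)` to training and splits the remainder validation-first with
   round-half-up (for n = 239 this yields 143/48/48; plain flooring of every
   ratio would give 143/47/49).
2. **Skull stripping.** Non-brain voxels are zeroed; shape and spacing are
   never changed. The default backend is a deterministic morphological
   extractor (below); an `external` backend shells out to a user-installed
   brain-extraction tool.
3. **VMD candidate masking.** Each axial slice is decomposed into K = 5
   band-limited modes; a chosen mode's local oscillation energy is
   thresholded into a candidate-lesion mask which multiplies the volume, so
   tissue with no lesion-like spectral signature is zeroed. The surviving
   intensities are scaled by the volume maximum into [0, 1].
4. **Patching.** Volumes are zero-padded (trailing ends) to multiples of the
   patch edge and tiled into cubic patches with 1-based reference IDs
   (`<subject>_patch_<serial>`, origin-lexicographic). All-zero patches are
   pruned but their IDs are recorded.
5. **Segmentation.** A 3D U-Net labels each retained patch; predictions are
   stitched back by reference ID with zeros re-substituted for pruned
   patches; overlapping voxels (overlap mode) combine by mean (probabilities)
   or strict-majority vote (labels, ties to background).
6. **Postprocessing and evaluation.** 26-connected components smaller than a
   minimum size are removed; predictions are scored against ground truth with
   IoU, DSC and ASSD, reported per subject with mean and sample (n−1)
   standard deviation.

## Variational mode decomposition

VMD decomposes an image f into K modes u_k, each compact in the frequency
domain around a learned center frequency ω_k, by minimizing the summed
bandwidth of the modes' analytic signals subject to Σ_k u_k = f. The solver
is the standard ADMM scheme in the 2-D frequency domain: a Wiener-type mode
update

    û_k ← (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α |ω − ω_k|²)

restricted to the analytic half-plane, a center-frequency update (first
moment of |û_k|² over the half-plane), and dual ascent
λ̂ ← λ̂ + τ (f̂ − Σ_k û_k). Iteration stops when the summed relative mode
change falls below `tol` or `max_iters` is reached. Modes are returned in
ascending ‖ω_k‖ and reconstructed by conjugate-symmetric completion of the
half-plane spectrum.

Numerical choices:

- **Half-plane convention.** The analytic-signal mask keeps ω₁ > 0 plus the
  ω₂ ≥ 0 half of the ω₁ = 0 line — including the DC bin, so a constant image
  is recovered exactly by the lowest mode. (Implementations that zero DC
  cannot represent the image mean in any mode.)
- **Defaults** follow the reference configuration: α = 1000, K = 5, τ = 0.5,
  tol = K × 10⁻⁶, iteration cap 500.
- **Initialization** `omega_init="uniform"` spaces K centers along the
  positive ω₁ axis at 0.5 (k + ½)/K; `"zero"` starts all centers at the
  origin. The solver contains no randomness, so results are bit-reproducible.
- **Degenerate inputs.** An all-zero image short-circuits to all-zero modes
  with `converged=True`; NaN input is rejected.

### Candidate mask

The mask marks voxels whose chosen mode oscillates strongly: the envelope is
the local RMS of the mode over a 5³ window, thresholded at the 75th
percentile of nonzero envelope values, binary-closed (3³ structure),
hole-filled (a candidate lesion is a volume, not an oscillation shell), and
cleaned of 26-connected components below 27 voxels. All policy parameters
are config-exposed.

The default mode index is 3, the experimentally best choice on real,
textured infarcts. On the synthetic phantoms the same envelope-separation
experiment selects mode 5: a smooth hypointense ellipsoid has no internal
texture, so its oscillation signature concentrates at its boundary in the
highest-frequency mode, and a mode-3 mask drops most lesion voxels while a
mode-5 mask retains nearly all of them. The phantom-study configurations
therefore set `vmd.mode_index: 5`.

## Skull stripping fallback

The morphological backend is Otsu thresholding → largest 26-connected
component → binary hole filling → closing with a radius-2 ball, then zeroing
intensities outside the resulting brain mask. The hole-filling step matters:
chronic infarcts are darker than the Otsu threshold, and without it they are
excised from the brain exactly like background — the opposite of what the
learned brain extractors this step stands in for would do, and fatal to any
downstream intensity-based segmentation. This fallback is adequate for
phantoms and smoke tests; for real scans a dedicated brain-extraction tool
via the `external` backend is recommended.

## 3D U-Net

Encoder levels apply two 3³ convolutions (each followed by ReLU and batch
normalization) and a 2³ max pool, doubling channels per level; the bridge
applies two convolutions; decoder levels up-convolve (2³, stride 2),
concatenate the matching encoder features, and apply two convolutions.
Dropout follows the second convolution block of every encoder and decoder
level. A final 1³ convolution maps to two channels (background, lesion) with
per-voxel softmax. Defaults: depth 4, 16 base filters, suitable for 64³
patches; the patch edge must be divisible by 2^depth.

Training minimizes the soft Dice loss
`1 − (2 Σ p·t + ε) / (Σ p + Σ t + ε)` (ε = 1.0, config-exposed) over whole
mini-batches with Adam. Reference defaults: batch 16, learning rate 0.001,
20 epochs, dropout 0.2. The epoch with the lowest validation loss is kept
when a validation set exists. All randomness (weight init, shuffling,
dropout) derives from `config.seed`, so training is bit-reproducible.

Implementation notes:

- The network is pure NumPy with hand-written backward passes; convolutions
  are im2col + a single BLAS GEMM per layer pass; the analytic gradients of
  the full softmax + Dice objective are verified against central finite
  differences in the test suite.
- The final layer's bias is initialized to (+2, −2), i.e. a foreground prior
  of ~2%. Lesions occupy a tiny fraction of brain volume; starting near the
  all-background solution keeps the soft-Dice denominator small and prevents
  the vanishing-gradient plateau a symmetric start produces under extreme
  class imbalance.
- Inference disables dropout and uses running batch-norm statistics, so
  repeated prediction is deterministic.

## Metrics

IoU = |X∩Y| / |X∪Y| and DSC = 2|X∩Y| / (|X|+|Y|) by voxel counting; the
identity DSC = 2·IoU/(1+IoU) holds exactly and is property-tested. ASSD is
the mean over both directions of minimum Euclidean distances (in mm, via
voxel spacing) between boundary voxel sets, computed with an exact Euclidean
distance transform. Boundaries use face (6-neighbor) adjacency with the
volume border counting as background — the conventional surface definition —
while connected components use the full 26-neighborhood. Components are
labeled in first-encounter raster order. Undefined measures (both masks
empty; any empty mask for ASSD) raise at the operation level and are
flagged, excluded and counted at the report level.

## Synthetic phantoms

A phantom is a centered bright ellipsoid ("brain", default semi-axes 0.42 ×
shape, intensity 100) with smooth low-frequency texture (Gaussian-filtered
noise, amplitude 5), containing 1–3 darker ellipsoidal lesions (intensity 30,
semi-axes 4–9 voxels, placed fully inside the brain without mutual overlap by
rejection sampling), plus additive Gaussian noise (σ = 5) clipped at zero.
Cohorts derive per-subject seeds from a master seed; lesion counts are drawn
with P(1, 2, 3) = (0.6, 0.3, 0.1), echoing the single-lesion majority of real
stroke cohorts.

What phantoms do not emulate: MRI bias fields, Rician noise statistics,
anatomical structure (ventricles, gray/white contrast), partial-volume
boundaries, and — importantly — the internal texture of real infarcts.
Passing the phantom study shows the pipeline's plumbing, optimization and
metrics are correct and that the network can learn an intensity/context rule;
it does not certify performance on clinical data.

## Scaled-down study conditions

Tests and the acceptance script exercise a complete study at reduced size:
10 phantom subjects of 64³ voxels, 32³ patches, a depth-2/4-filter U-Net
(batch 4, learning rate 0.01, 25 epochs), VMD capped at 200
iterations per slice, and candidate masking from mode 5. These sizes are the
package's chosen default experiment: large enough that the test subjects are
disjoint from training and the Dice target is meaningful, small enough to run
on a single CPU core. The overfit check trains a depth-2/4-filter network on
one 64³ phantom patch (repeated four times per epoch, learning rate 0.01,
batch 1) and expects a training Dice loss below 0.1 well within 30 epochs.

## Known limitations

- Slice-wise 2-D VMD along one axis; no full-3D decomposition.
- The morphological skull strip is a fallback, not a validated brain
  extractor.
- The grid patch mode (stride = patch size) is the default; overlap mode
  (stride = patch − overlap, clamped final origins) is provided but the two
  bookkeeping schemes imply different patch counts for the same volume.
- Single modality (T1); no multi-modal fusion.
- CPU-only NumPy training: practical for the scaled-down studies here, not
  for full-resolution clinical cohorts.
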