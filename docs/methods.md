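# Methods

## The objective

The training loss combines a foreground-masked pixel term and a
shape term:

* **Foreground estimation.** The mask M comes from the *target* fluorescence
  volume, never the prediction: T is the Otsu threshold of the target's
  256-bin histogram over [min, max], and M = [Y ≥ T] (the comparison is
  inclusive). Otsu maximizes the inter-class variance over every cut between
  adjacent bins; when several cuts tie (this happens exactly when the bins
  between them are empty) the lowest threshold is returned, with a 1e−9
  relative tolerance on the maximum so that floating-point noise in the
  cumulative sums cannot flip the choice. The returned T is the lower edge
  of the first foreground bin, so `Y >= T` reproduces the histogram split
  exactly. A constant volume has no threshold and raises
  `DegenerateHistogramError` — callers decide whether that means all
  foreground or all background.

* **Masked MSE.** `L_MMSE = Σ M (Y − Ŷ)² / Σ M`. Undefined on an empty
  mask; the implementation raises `EmptyForegroundError` rather than
  silently returning 0, because a silent 0 would look like a perfect score.

* **Soft-thresholded Dice.** The prediction is soft-thresholded with the
  normalized tunable sigmoid `σ_k(x) = (x − kx)/(k − 2k|x| + 1)`, an odd,
  bounded map of [−1, 1] onto itself with fixed points 0 and ±1; k = 0 is
  the identity and k → −1 approaches a step at 0. Admissible k is the open
  interval (−1, 1): at |k| ≥ 1 the denominator vanishes inside the domain.
  The Dice loss is `1 − 2Σ(σ·M)/(Σσ + ΣM + ε)` with ε > 0 smoothing the
  empty-mask limit.

* **Total.** `L = λ·L_MMSE + (1−λ)·L_Dice`, λ ∈ [0, 1]. Defaults λ = 0.5
  (equal weight, exposed in config), k = −0.9 (strongly sharpening but far
  enough from −1 that gradients stay finite), ε = 1e−6.

### How the prediction enters σ_k's domain

σ_k is defined on [−1, 1]; a [0, 1]-normalized prediction has to be brought
into that domain, and where the sigmoid's transition sits is the largest
open design choice in the objective. Three policies are implemented:

* `otsu_center` (default): recentre about the target's Otsu threshold c = T,
  map with scale max(c, 1−c) onto [−1, 1] (clipped), apply σ_k, map back to
  [0, 1]. The transition then coincides with the threshold that defined the
  mask the Dice term compares against, which is the only self-consistent
  placement: a prediction that equals the target scores σ ≈ 1 exactly on
  mask voxels.
* `fixed_half`: same construction with c = 0.5.
* `direct`: apply σ_k to the clipped prediction as-is; for negative k the
  transition then sits just above zero intensity. Measured head-to-head on
  the synthetic benchmark, this variant collapses background as well as the
  default but loses several dB more foreground PSNR — the near-zero
  transition makes early-training foreground gradients huge (σ′(0) =
  (1−k)/(1+k) = 19 at k = −0.9) and destabilizes the masked-MSE equilibrium
  — so it is kept as an option, not the default.

During training the mask is recomputed per patch (with a guard: if the
patch's Otsu threshold falls below half the whole-volume threshold, the
patch histogram has no genuine foreground/background bimodality — it is
noise or halo only — and the whole-volume threshold is used instead). The
guard matters: without it, spurious low patch thresholds label background
noise as foreground, both loss terms then supervise noise upward, and
training diverges. `mask_scope="volume"` uses the whole-volume mask
throughout.

## Differentiation and the backbone

No autodiff framework is assumed: the package carries a ~300-line
reverse-mode tape over numpy (`spotlight3d._autodiff`) implementing exactly
the ops the losses and the network need (broadcasting arithmetic, |x|,
ReLU, clip, reductions, same-padded 3D convolution, 2× average pooling, 2×
nearest-neighbour upsampling). Every op's gradient is tested against
central finite differences.

The backbone is a deliberately small 3D U-net-style network — `depth`
encoder levels of two 3³ convolutions + ReLU with 2× average pooling,
a bottleneck, a mirrored decoder with additive skips, and a linear 1×1×1
output head; channel width doubles per level from `base_channels`
(defaults: depth 2, 8 channels, ~15k parameters). It is a stand-in at desk
scale for the much larger label-free models used in production: the loss,
not the architecture, is the object of study here. Patch spatial dimensions
must be divisible by 2^depth.

Full volumes are predicted tile-wise with a floored-Hann blending window
(single-tile regions reproduce the direct forward pass exactly; overlaps
blend linearly). The network output is linear, and predictions are
intensities, so the assembled volume is clamped to the valid normalized
range [0, 1]. The clamp is not cosmetic: the Dice term's gradient vanishes
once background falls below the sigmoid's clipped domain, so nothing in the
objective anchors background at exactly zero — raw outputs drift to
arbitrary negative values in well-suppressed regions, and the clamp maps
that entire regime to the intended "background ≈ 0" reading.

## Training protocol

Adam (lr 1e−3, β = 0.9/0.999), 60 epochs × 12 steps × batch 2 of 16³
patches by default; all randomness flows through `numpy.random.default_rng`
seeded from the config, so runs are bit-reproducible. Patches are sampled
uniformly but must contain at least one foreground voxel under the
whole-volume mask — background-only patches are skipped and counted
(L_MMSE is undefined on them, and they carry no signal for either
objective). Volumes are min–max normalized per volume before training;
normalization parameters are stored in checkpoints for inversion.
Validation loss (same mode as training, plus always plain MSE for
cross-mode comparability) is recorded every epoch; the best-by-validation
and final checkpoints are written when an output directory is given.

The comparison experiment (`compare_objectives`) is the controlled
contrast: per seed, an identical train/held-out split, identical backbone
initialization and identical schedule are used for a plain-MSE run and a
Spotlight run; only the loss differs. Held-out volumes are scored at the
pixel level (PSNR and 3D SSIM, whole-image and foreground-restricted; FSC
resolution; background mean |intensity|), the segmentation level (Otsu +
EDT + watershed instance segmentation, AP@IoU against the generator's
ground-truth labels), and the feature level (morphological profile cosine
distance), plus the post-hoc intensity-threshold sweep.

## Synthetic data

The generator emulates the statistical regime the objective targets, not
optics: non-overlapping axis-aligned ellipsoidal nuclei (per-axis radii
uniform in 4–7 voxels; rotation omitted so analytic oracles stay simple)
painted at uniform intensities 0.6–0.9 on a zero background; the target is
that clean scene blurred with an anisotropic Gaussian (σ = 2.5 axial / 1.0
lateral — the axial elongation "halo"), plus a 0.1 background offset,
σ = 0.02 Gaussian noise, and a zero-mean low-frequency intensity ramp
(amplitude 0.05). The separability constraint (foreground min > offset +
3·noise SD) is validated at construction so Otsu masks of test fixtures are
meaningful by design. The paired input modality is a fixed deterministic
transform of the clean scene — edge-enhanced, contrast-inverted, with
independent noise — chosen so the mapping is learnable by the small
backbone in minutes yet is not the identity. Labels mark each nucleus's
*pre-blur* support, so segmentation scores penalize halo-inflated
predictions.

What this generator does *not* model: textured nuclei, touching or rotated
instances, depth-dependent aberrations, realistic brightfield contrast,
camera noise statistics. Passing tests therefore demonstrate the objective's
behaviour under controlled foreground/background statistics, not
performance on real microscopy.

## Evaluation stack

* **PSNR**: `10 log10(R²/MSE)` with R the *target's* dynamic range
  (prediction-independent); identical volumes report a capped 100 dB
  sentinel with a flag. Masked variant restricts the MSE to mask voxels.
* **3D SSIM**: standard structural similarity with cubic windows (default
  7³, K1 = 0.01, K2 = 0.03 over the target's range) computed via
  scikit-image; the masked variant averages the local SSIM map over the
  mask. This is a plain 3D SSIM, a stand-in for microscopy-specific
  structural-similarity variants, not a reproduction of any of them.
* **FSC/FRC resolution**: normalized cross-correlation of the two volumes'
  Fourier coefficients accumulated over concentric frequency shells
  (3D shells by default; per-slice 2D rings as an option), DC excluded,
  corner frequencies beyond Nyquist excluded. The resolution estimate is
  the real-space period at the first crossing below the 1/7 criterion,
  linearly interpolated between shells; curves that never cross report the
  2-voxel Nyquist floor with a flag.
* **Instance segmentation**: Otsu binarization, Euclidean distance
  transform, Gaussian-smoothed distance map, seeds at local maxima with a
  minimum separation (default 4 voxels ≈ the expected nucleus radius),
  watershed of the negative distance map inside the mask, removal of
  instances under 27 voxels (3³), consecutive relabeling. Constant volumes
  yield an empty labeling with a warning instead of an exception, so
  evaluation never crashes on an all-background prediction. External
  segmenters plug in through a one-callable adapter.
* **AP@IoU**: `AP = TP/(TP+FP+FN)` after one-to-one matching at each IoU
  threshold (grid {0.5, 0.6, 0.7, 0.8, 0.9}) — the instance-segmentation
  convention of the cell-segmentation literature, *not* the ranked-detection
  PR-curve area. Matching is greedy by descending IoU with (gt, pred)-id
  tie-breaks; Hungarian optimal matching is available and tested to agree
  with greedy on all shipped fixtures. Both labelings empty scores 1.0;
  exactly one empty scores 0.0.
* **Profiles**: nine fixed-order per-instance features (volume, equivalent
  diameter, exposed-voxel-face surface area, bbox extent, axial/lateral
  bbox elongation ratio, sphericity, mean/SD/integrated intensity; schema
  version 1), aggregated per volume by the median across instances (mean
  optional), compared by cosine distance (optionally z-scored by
  target-derived reference statistics). Profiles for prediction and target
  are measured on their own independent segmentations, mirroring how the
  comparison would be run on real data without shared labels; a
  shared-labels mode covers intensity-only contrasts. The feature set is a
  compact stand-in for dedicated profiling batteries; sphericity rounds out
  the shape block.

## Problem sizes

The shipped end-to-end experiment uses 16 volumes of 64³ with 6 nuclei
(14 train, 2 held out per seed; three seeds; 60 epochs ≈ 1440 gradient
steps per run). These sizes were chosen so the complete two-objective,
three-seed comparison runs in roughly a quarter of an hour on a single CPU
core while the learned mappings are clearly converged (plain-MSE validation
loss plateaus well before epoch 60).

## Known limitations

* The Dice/MMSE equilibrium deliberately deviates from the degraded target
  inside the mask (halo suppression, mild sharpening near the threshold),
  so foreground PSNR of the Spotlight model trails the pure-MSE model by a
  few dB on this synthetic family even as background collapses by two
  orders of magnitude and downstream segmentation/profiling match or
  improve. The size of that gap depends on how much of the Otsu mask is
  halo rather than nucleus.
* The backbone is far smaller than production label-free networks; absolute
  metric values are not comparable to published benchmarks.
* The trainer is CPU-only and single-device by design.
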