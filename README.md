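# spotlight3d

Foreground-aware training and evaluation for 3D virtual staining.

## The problem

Virtual staining (in-silico labeling) predicts fluorescence volumes from
transmitted-light microscopy with an image-to-image regression network.
Conventional training minimizes a voxel-wise loss such as MSE over the whole
stack — but in 3D fluorescence data the background dominates the voxel count
and carries only noise and optical artifacts (notably the axially elongated
"halo" of the point-spread function). A whole-volume pixel loss therefore
spends most of its capacity reproducing background noise, and the
predictions inherit the segmentation difficulties of the raw fluorescence.

`spotlight3d` implements a foreground-aware objective for this problem,
together with the full evaluation stack needed to measure its effect at the
pixel, segmentation, and feature level, and a seeded synthetic generator of
paired volumes so the whole pipeline trains and tests on a laptop CPU with
no downloads.

## The objective

Let Y be the target fluorescence volume, Ŷ the prediction, and T the Otsu
threshold of Y's intensity histogram (the cut maximizing inter-class
variance). The binary foreground mask is M = [Y ≥ T]. Training minimizes

```
L = λ · L_MMSE + (1 − λ) · L_Dice

L_MMSE = (1/ΣM) Σ M · (Y − Ŷ)²                    masked pixel loss
L_Dice = 1 − 2 Σ(σ_k(Ŷ)·M) / (Σσ_k(Ŷ) + ΣM + ε)   soft-thresholded shape loss
σ_k(x) = (x − kx) / (k − 2k|x| + 1)                normalized tunable sigmoid
```

The masked MSE restricts supervision to informative voxels; the Dice term
scores the soft-thresholded prediction against the mask and favours
spatially coherent, artifact-free foreground. All terms are differentiable
in Ŷ (the package ships a compact reverse-mode autodiff over numpy, plus a
small 3D U-net-style backbone and a deterministic trainer, so no deep
learning framework is required).

Defaults: λ = 0.5, k = −0.9, ε = 1e−6; the sigmoid transition is recentred
at the target's Otsu threshold (`center_policy="otsu_center"`). See
`docs/methods.md` for the reasoning and alternatives.

## Worked example

```python
import numpy as np
from spotlight3d import (SynthConfig, SpotlightLossConfig, generate_sample,
                         normalize_volume, spotlight_loss)

sample = generate_sample(SynthConfig(seed=7))       # 64^3, 6 nuclei
target, _ = normalize_volume(sample.target_volume)
noisy_guess = np.clip(target + 0.1 * np.random.default_rng(0)
                      .normal(size=target.shape), 0, 1)

lv = spotlight_loss(target, noisy_guess, SpotlightLossConfig())
print(f"total {lv.value:.4f}  mmse {lv.components['mmse']:.4f}  "
      f"dice {lv.components['dice']:.4f}")
```

prints

```
total 0.3077  mmse 0.0097  dice 0.6058
```

The masked-MSE component is the mean squared error over the ~2% of voxels
inside the target's Otsu mask (0.0097 ≈ the injected noise variance). The
Dice component is large for this deliberately noisy guess: the added noise
lifts many of the dominant background voxels into the sigmoid's transition
zone, inflating Σσ_k(Ŷ) against a small mask — exactly the behaviour that
drives background suppression during training. The total is their convex
combination with λ = 0.5.

A full training-and-comparison run from the shell:

```bash
spotlight simulate --seed 1 --out data/            # paired TIFFs + manifest
spotlight compare --data data/ --seeds 101,102,103 --out compare.csv
```

`compare.csv` holds one row per (seed, objective) with foreground-restricted
PSNR/SSIM, FSC resolution, background mean |intensity|, watershed AP@IoU,
profile cosine distance, and the post-hoc threshold-sweep AP range. Other
subcommands (`train`, `predict`, `evaluate`, `segment`, `sweep`, `profile`)
expose the individual stages.

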