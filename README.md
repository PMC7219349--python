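# fuzzseg

Robust fuzzy clustering segmentation for noisy raster images.

`fuzzseg` is for anyone who needs to partition a heavily corrupted
single-channel (or multi-channel) image — remote-sensing scenes, medical
slices, industrial inspection frames — into C intensity classes without
training data. Plain fuzzy c-means (FCM) treats each pixel in isolation and
falls apart under impulse or strong Gaussian noise; this package provides
the spatial FLICM family of segmenters and, as its main algorithm, a
**feature-saliency local fuzzy clustering** model that combines three
robustness mechanisms:

* a fuzzy local-information factor whose neighbor weights
  u_iβj = (1 − z_βj)^m / (z_βj d̃_iβ + 1) let confident neighbors stop
  penalizing their class,
* per-pixel **feature saliency** s_ijl ∈ (0,1) arbitrating between a
  class-specific mean μ_jl and a common background mean ε_l, with a KL
  penalty γ Σ z·KL(s‖ρ) toward feature priors ρ_l,
* a KL-regularized membership update
  z_ij ∝ π_j H_ij^α exp(−η_ij/λ), where H_ij is the median of the
  neighbors' memberships — a median filter acting inside the iteration.

All update equations are closed-form stationary points of one objective
(verified numerically in the test suite). Everything is deterministic given
an integer seed. See `docs/methods.md` for the full model, the parameter
table and the numerical choices.

## Worked example

Segment a 2-class 64×64 phantom corrupted by 20% salt-and-pepper noise and
compare against plain FCM:

```python
from fuzzseg import (FeatureSaliencyFLICM, FCM, make_phantom,
                     add_salt_pepper, score_segmentation)

ph = make_phantom(64, 64, 2, (40, 200), "stripes", seed=0)
noisy = add_salt_pepper(ph.image, 0.2, seed=1)

res = FeatureSaliencyFLICM(noisy, 2).fit(seed=0)
print(res.summary())
score = score_segmentation(ph, res.label_map())
print(f"MCR = {score.mcr:.3f}%   PSNR = {score.psnr:.2f} dB")
print(f"FCM MCR = {score_segmentation(ph, FCM(noisy, 2).fit(seed=0).label_map()).mcr:.3f}%")
```

prints

```
Feature-saliency local fuzzy clustering results
================================================
pixels: 4096   classes: 2   features: 1
lambda=1000  gamma=1000  alpha=2  m=2  window=3
iterations: 300   converged: False
final objective: 1.64907e+07
class means mu (intensity units):
  class 0: 204.11   prior pi=0.504
  class 1: 36.94   prior pi=0.496
background means eps: 113.15
feature weights rho:  0.876

MCR = 0.684%   PSNR = 25.74 dB
FCM MCR = 10.010%
```

Despite a fifth of all pixels being pure impulses, the recovered class
means (36.9, 204.1) sit within a few gray levels of the true (40, 200) and
only 0.68% of pixels are mislabeled, versus 10% for FCM. (The membership
field here oscillates in a tiny limit cycle instead of meeting the 10⁻⁴
convergence norm — `converged: False` with a good segmentation is common
under heavy impulse noise.) MCR is the misclassification rate after optimal
label matching; PSNR compares the clean image with the class-mean
reconstruction of the predicted labels.

## Command line

```bash
fuzzseg phantom --height 64 --width 64 --clusters 2 --levels 40,200 \
        --noise sp --density 0.2 --seed 0 --out-dir run/
fuzzseg segment --in run/noisy.png --algorithm fs --clusters 2 \
        --truth run/truth.png --seed 0 --out-dir run/fs/
fuzzseg benchmark --algorithms fcm,flicm,improved_flicm,fs --seeds 0,1,2 \
        --noise gaussian --sigma 57 --out-dir bench/
```

Algorithms: `fcm`, `flicm`, `improved_flicm` (membership-constrained
FLICM), `fs` (the feature-saliency segmenter). Every run writes a
`run_config.json` echo of all resolved parameters, so results are
reproducible from their artifacts alone.

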