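# Methods

## The model

`fuzzseg` segments a raster image by soft clustering of its pixel intensity
vectors. A pixel i carries a feature vector x_i ∈ R^D (D = 1 for the 8-bit
grayscale reference case); a segmentation into C classes is a membership
matrix z ∈ [0,1]^{N×C} with unit row sums, hardened at the end by the
maximum-membership rule.

The main segmenter (`FeatureSaliencyFLICM`) minimizes

    J = Σ_i Σ_j z_ij (d_ij + G_ij)
      + λ Σ_i Σ_j z_ij log(z_ij / π_j)
      + γ Σ_i Σ_j Σ_l z_ij [ s_ijl log(s_ijl/ρ_l)
                            + (1−s_ijl) log((1−s_ijl)/(1−ρ_l)) ]

over memberships z, class means μ ∈ R^{C×D}, class priors π, background
means ε ∈ R^D, feature weights ρ ∈ (0,1)^D and saliencies
s ∈ (0,1)^{N×C×D}, where

    d_ij = Σ_l [ s_ijl (x_il − μ_jl)² + (1−s_ijl)(x_il − ε_l)² ]
    G_ij = Σ_{β∈N_i} u_iβj Σ_l [ s_ijl (x_βl − μ_jl)² + (1−s_ijl)(x_βl − ε_l)² ]
    u_iβj = (1 − z_βj)^m / (z_βj d̃_iβ + 1).

Three ideas are combined:

* **Feature saliency.** s_ijl arbitrates, per pixel/class/feature, between
  a class-specific explanation (distance to μ_jl) and a common-background
  explanation (distance to ε_l); ρ_l is the prior probability that feature
  l is discriminative at all. The γ-weighted KL term regularizes s toward
  ρ. In the D = 1 grayscale case the machinery still matters: saliency
  softens the penalty for pixels (noise impulses in particular) that no
  class mean explains well.
* **Local spatial information.** G_ij is the neighborhood analogue of d_ij,
  with neighbor weights u_iβj that shrink both with the spatial distance
  d̃_iβ and with the neighbor's own confidence z_βj in class j: a neighbor
  that firmly belongs to class j stops penalizing it (the (1−z_βj)^m
  factor), and a confident distant neighbor counts less than a confident
  close one (the z_βj d̃_iβ + 1 denominator).
* **KL-regularized memberships.** The λ-weighted entropy term replaces the
  fuzzifier exponent on z in the data term, giving an exponential
  (softmax) membership update instead of the inverse-power FCM form, and
  pulls memberships toward the class priors π, which accommodates
  unbalanced class sizes.

## Updates and the iteration schedule

All updates are exact coordinate-wise stationary points of J with the
neighbor weights u frozen at the previous memberships (verified numerically;
see below):

    t_ijl = [(x_il−ε_l)² + Σ_β u_iβj (x_βl−ε_l)²]
          − [(x_il−μ_jl)² + Σ_β u_iβj (x_βl−μ_jl)²]
    s_ijl = σ( t_ijl/γ + logit ρ_l )                       (logistic σ)
    η_ij  = Σ_l { s_ijl [(x_il−μ_jl)² + Σ_β u (x_βl−μ_jl)² + γ log(s_ijl/ρ_l)]
                + (1−s_ijl)[(x_il−ε_l)² + Σ_β u (x_βl−ε_l)² + γ log((1−s_ijl)/(1−ρ_l))] }
    z_ij  ∝ π_j H_ij^α exp(−η_ij/λ)                        (row-normalized)
    μ_jl  = Σ_i z_ij s_ijl (x_il + Σ_β u_iβj x_βl) / Σ_i z_ij s_ijl (1 + Σ_β u_iβj)
    ε_l   = same form with weights z_ij (1−s_ijl), summed over i and j
    ρ_l   = N⁻¹ Σ_i Σ_j z_ij s_ijl ,   π_j = N⁻¹ Σ_i z_ij

H_ij is the per-class **median of the neighbors' memberships** (center
excluded; even counts average the two central order statistics; a pixel
with no neighbors keeps its own membership). Raising H_ij can only raise
z_ij — the membership update is monotone in the median field — so the
α-exponentiated median acts as an impulse-robust smoother applied inside
the iteration rather than as a post-hoc filter.

One iteration runs: median field H → saliency s → membership z → model
(μ, ε, ρ, π), and the loop stops when max_ij |Δz_ij| < δ or after τ_max
iterations (non-convergence is reported via a flag, not an error).
Initialization: ρ_l = 1/D, π_j = 1/C, then a seeded FCM run supplies the
initial memberships and class means; ε and the diagnostic variances are the
global feature means/variances. Class variances σ², ν² are computed at
initialization and carried as diagnostics only — no update equation or
distance term uses them, since the distances are unscaled squared
distances, not Gaussian log-densities. No variance-scaled mode is
implemented.

## Baselines

* **FCM** — classic fuzzy c-means with fuzzifier m.
* **FLICM** — FCM plus the fuzzy factor
  G_ij = Σ_β (d̃_iβ+1)⁻¹ (1−z_βj)^m ‖x_β−v_j‖², with the classic FCM
  center update. The 1/(d̃+1) weighting is the default (it avoids
  overweighting distance-1 neighbors); `inverse_distance=True` selects the
  bare 1/d̃ variant. With the spatial term disabled (`window=None`) FLICM
  shares FCM's exact code path and reproduces it bit-for-bit.
* **Membership-constrained FLICM** (`MembershipConstrainedFLICM`) — the
  fuzzy factor's neighbor weight becomes (z_βj d̃_iβ + 1)⁻¹(1−z_βj)^m and
  the center update is the exact Lagrangian stationary point, mixing each
  pixel with its u-weighted neighborhood.

## Parameters

| parameter | default | units / range | role |
|---|---|---|---|
| λ | 10³ | squared 0–255 intensity | membership-entropy weight; larger → softer, prior-driven memberships |
| γ | 10³ | squared 0–255 intensity | feature-selection weight; larger → saliencies stay near ρ |
| α | 2.0 | ≥ 0 | exponent on the membership median H; 0 disables spatial smoothing of z |
| m | 2.0 | > 1 | fuzzifier in neighbor weights and baselines |
| window | 3 | odd ≥ 3 | neighborhood side (3×3 or 5×5 in practice); truncated at borders |
| δ (`tol`) | 10⁻⁴ | membership units | max-norm convergence threshold on z |
| τ_max (`max_iter`) | 300 | iterations | cap; non-convergence is flagged |

λ and γ are calibrated against squared distances on the 0–255 intensity
scale; features are therefore kept in native storage units and not
rescaled (a deliberate default — rescaling to [0,1] would require scaling
λ, γ by ~255²).

## Numerical choices

* All softmaxes are computed in log space (shift by the row maximum), so
  distance costs of order 255²·|N_i| cannot underflow a row.
* s, ρ, H, z and π are floored/ceilinged at 10⁻¹² (ρ at 10⁻⁶) away from
  {0, 1} before entering any logarithm or denominator. The weight
  denominators z_βj d̃ + 1 ≥ 1 are intrinsically safe.
* A pixel at zero FCM dissimilarity to some class gets crisp membership
  there, first index on ties; argmax labeling also breaks ties toward the
  lowest class index. Both rules are deterministic.
* A class whose total (saliency-weighted) membership mass vanishes keeps
  its previous mean and a RuntimeWarning is emitted; this happens
  legitimately on degenerate inputs (e.g. a constant image, where any
  labeling is valid).
* One integer seed drives the only random element (FCM membership
  initialization; plus layout/noise draws in the generators); everything
  else is deterministic, so runs are bitwise reproducible given a seed.
* Boundary policy is truncation: border pixels simply have fewer
  neighbors, and every neighbor sum is over the in-bounds set. Any odd
  window ≥ 3 is accepted even on grids smaller than the window (the
  neighbor set truncates; a 1×1 image has empty neighbor sets).

## Synthetic phantoms and what the tests do (and do not) show

The generator produces piecewise-constant C-class images (horizontal
stripes, quadrants, or Voronoi blobs; every class ≥ 5% of pixels) with
known gray levels, corrupted by: additive Gaussian noise of a given
standard deviation on the 0–255 scale; exact-count salt-and-pepper noise
(round(density·N) pixels set to the range extremes, salt/pepper split
evenly at random); multiplicative speckle x·(1+n) with n ~ N(0, (σ/255)²);
or Gaussian followed by salt-and-pepper. Noise levels quoted as
"variances" in the segmentation literature at magnitudes like 57 or 140
are treated as standard deviations on the 0–255 scale (true variances of
that size would perturb an 8-bit image imperceptibly); a
`sigma_is_variance` flag gives the literal reading.

These phantoms have exactly piecewise-constant classes, sharp straight
boundaries, and spatially white noise. Real remote-sensing or medical
images have textured classes, intensity gradients, correlated noise and
partial-volume boundaries; performance on the phantoms therefore
demonstrates noise robustness of the optimization, not segmentation
quality on any particular real modality.

Default study conditions used by the test suite and the acceptance script:
2-class 64×64 phantoms at levels (40, 200) for the robustness comparison
(20% salt-and-pepper; Gaussian σ = 57; 10 seeds), 3-class 64×64 phantoms at
(50, 128, 210) with σ = 10 for parameter recovery (5 seeds), and a clean
32×32 2-class phantom for exact recovery.

## Evaluation protocol

* **MCR** (percent) counts disagreeing pixels after choosing the label
  permutation that maximizes agreement — exhaustive search for C ≤ 6,
  Hungarian assignment beyond (the two agree wherever both run; this is
  asserted in the tests). Without matching, MCR of a clustering would
  depend on arbitrary label identities.
* **PSNR** for segmentation quality is 10·log₁₀(peak²/MSE) between the
  clean image and the class-mean reconstruction of the predicted labels
  (each pixel replaced by its predicted class's mean). A perfect
  segmentation of a piecewise-constant phantom reconstructs exactly; the
  infinite PSNR is serialized as the string `"inf"`. Measuring against the
  clean image rather than the noisy input makes the score a property of
  the partition alone.

## Verification of the closed forms

The derivations behind the printed update equations in this literature are
easy to garble (index typos, dropped exponents, self-referential
normalizers). The implementation therefore treats the objective J as the
single source of truth and asserts, on dozens of random small instances,
that every closed-form update (s, μ, ε, ρ, π) annihilates the numeric
central-difference partial derivative of J — for π, the directional
derivatives within the probability simplex — to ~10⁻⁹ relative, far inside
the 10⁻⁵ test tolerance. The instances use intensities on a [0, 30] scale:
at full 0–255 scale the saliency logistic saturates (|t|/γ up to ~600) and
the clamped entries become boundary optima where an interior gradient test
is meaningless; on the unsaturated scale the test exercises the genuine
stationarity of the smooth objective. The same consideration applies to
ρ's clamp, which only engages when s saturates.

## Known limitations

* The objective is non-convex and the alternating scheme only guarantees
  coordinate-wise stationarity; different seeds can reach different local
  optima (the FCM warm start makes this rare on well-separated phantoms).
* The membership iteration with the median field can enter small limit
  cycles instead of meeting the 10⁻⁴ max-norm criterion; the iteration cap
  then returns the last state with `converged=False`, which is usually a
  perfectly good segmentation.
* Per-class covariances are not modeled; classes are separated by means
  only, so classes distinguished by variance or texture are out of reach.
* The median field is the only spatial postprocessing; no Markov-random-
  field smoothing or boundary-aware regularization is provided.
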