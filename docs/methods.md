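# Methods

## Model

The package refines 22 lumbar landmarks (L1–L5 corner quadruples in
UL, UR, LL, LR order; S1 upper-endplate endpoints) from per-landmark
heatmaps. Coordinates are 0-based continuous pixels, x along columns, y
along rows downward, pixel centers at integers. A configuration is the
44-vector (x₁…x₂₂, y₁…y₂₂).

### Point-distribution model

Training shapes are aligned by generalized Procrustes analysis: each shape
is similarity-fitted (scale > 0, rotation, translation; reflections
excluded — lateral radiographs have fixed chirality) to the running mean,
which is re-estimated, centred at the origin and normalized to unit
Euclidean norm, until it changes by less than 1e-10 (at most 100 passes;
non-convergence warns rather than fails). The Procrustes mean is defined
only up to rotation; the gauge is fixed by rotating the converged mean so
its dominant principal axis lies along +y with L1 above S1. This makes the
mean invariant to input ordering and to similarity pre-transforms of
individual inputs. The convention is unstable only for configurations with
nearly isotropic principal axes, which spine shapes are far from.

Aligned shapes are projected onto the tangent plane at the mean
(y′ = y / (y·x̄)) before PCA. The projection makes every deviation exactly
orthogonal to x̄, which linearizes the statistics and makes shapes
synthesized from coefficients exact fixed points of the constraint
iteration below. PCA uses the sample covariance (1/(n−1)) about the mean;
all modes with eigenvalue above 1e-12 of the leading one are retained (at
most 43), with a deterministic sign convention (largest-magnitude component
positive). The number of modes actually used, n_P, is chosen at correction
time.

### Slip augmentation

Spondylolisthesis is under-represented in training populations, biasing the
shape model toward normal anatomy. Artificial slips translate the landmark
block of vertebrae V_start..V_end (1..5 = L1..L5, 6 = S1) rigidly by
α·β·(UR* − UL*), where (UL*, UR*) are the top two points of the first moved
vertebra, α ∈ {−1, +1}, and β ∈ [0, β_max] with β_max = 0.3. The slip
direction follows the upper-endplate vector, which in a lateral view
approximates the anterior–posterior slip axis; this is a documented
convention, not an anatomical claim. Sampling is uniform over V_start,
V_end ≥ V_start (optionally fixed to 6), α, and β; `balance_training_set`
appends augmented copies of randomly chosen normal shapes until the slipped
fraction reaches a target (default 0.15). Only coordinates are generated —
no image synthesis.

### Shape constraint

`constrain_shape` projects an image-frame configuration Y onto the model:
iterate x = x̄ + P b; pose T = argmin Σ‖T(x) − Y‖²; y = T⁻¹(Y); tangent
projection y′ = y/(y·x̄); b = Pᵀ(y′ − x̄), optionally clamped to
±clamp_k·√λ (default clamp_k = 3, the usual point-distribution-model
convention; disable with `clamp_k=None`), until ‖Δb‖ < 1e-6 or 50
iterations. A vanishing y·x̄ denominator raises rather than divides; it
cannot occur for configurations anywhere near the mean. The result
X = T(x̄ + P b) is equivariant to similarity transforms of Y and idempotent
up to the tolerance.

### Correction loop

Initial landmarks are per-channel argmaxes (row-major tie-break; an
all-zero channel yields the channel center and an "undetected" flag).
Each channel has its own affine mapping image = offset + pos/scale, so
sub-image crops of any size or magnification are supported.

Per iteration (default 30):

1. **Gradient update.** Channels are max-normalized (default; makes the
   step size comparable across detector confidence levels) and filtered
   with 3×3 Sobel kernels scaled by 1/8 — exact derivatives on affine
   surfaces — with replicate borders. Magnitude/orientation are sampled at
   the current position by bilinear interpolation of the Cartesian gradient
   components (never of angles, which wrap at ±π). The landmark moves by
   μ·m_h·(cos o_h, sin o_h)/scale. The proportional-ascent rule is the
   minimal law consistent with using (m_h, o_h, μ) as distance and
   direction; division by the channel scale keeps μ resolution-independent.
   A landmark outside its channel window receives no gradient move but
   still participates in the shape step, which can relocate it from the
   other landmarks.
2. **Shape reorganization** with n_P modes as above.

The loop stops early when the largest per-landmark displacement of a full
iteration falls below 0.1 px (max, not mean, displacement; configurable).
Defaults n_P = 20 and μ = 0.02 are the grid-search-selected operating
point; `grid_search` reselects them on a validation set by minimizing
AE_max (ties prefer smaller n_P, then smaller μ).

### Snap-back post-processing

The shape step displaces even well-detected landmarks slightly off their
argmaxes, raising the mean error while lowering the maximum. When enabled
(γ ≥ 0), each final landmark returns to its channel's global argmax if
closer than γ·Ẽ_a, with Ẽ_a the allowable error (below) computed once from
the corrected configuration before any snap — making the result independent
of landmark order. The strict inequality makes γ = 0 an exact no-op, and
the snapped set is monotone (nested) in γ.

### Evaluation indices

E_ij is the Euclidean point error (pixels; millimetres when a pixel spacing
is known). Per image: E_max,i, E_mean,i; dataset averages AE_max, AE_mean.
The allowable error E_a,i is 20% of the mean of the 21 vertebral edge
lengths (four sides of each L1–L5 quadrilateral, plus the S1 endplate
segment); NE_max/NE_mean divide per-image errors by E_a,i before averaging,
removing image-scale effects. The interval histogram bins images by
E_max,i into (k−1, k]·E_a,i for k = 1..5 plus an overflow bin; upper edges
are inclusive. Paired two-sided t-tests compare per-image indices between
methods; an all-zero difference vector reports p = 1 and a zero-variance
nonzero mean reports an infinite statistic with p = 0, both flagged
degenerate.

## Synthetic data

The generator emulates the *label geometry* of lateral lumbar radiographs,
not the images: five tilted rectangles plus an endplate segment stacked
along a smoothly curved centerline. Dimensions (pixels; defaults chosen for
a ~200 px spine in a 320×256 frame at 0.17 mm/px):

| parameter | default | meaning |
|---|---|---|
| vertebra_width_px / height_px | 48 / 30 | mean body size |
| aspect_cv | 0.10 | per-subject shared height factor |
| disc_cv | 0.20 | per-subject shared gap factor |
| width_cv, height_cv | 0.04 | independent per-vertebra residuals |
| gap_px, gap_cv | 10, 0.08 | disc spacing and residual |
| curvature_amplitude_px | 12 | lordotic bow of the centerline |
| tilt_spread_rad | 0.04 | per-vertebra tilt noise |
| landmark_jitter_px | 0.5 | labeling noise per coordinate |
| spondylolisthesis_fraction | 0.15 | slip prevalence (β ∈ [0.05, 0.3]) |

Vertebral dimensions within a subject are strongly correlated, so size
variation is parametrized as shared per-subject factors (aspect, disc
height) plus small independent residuals; this concentrates population
variance in a few leading modes, as in real morphometric data. The
labeling jitter emulates inter-rater ground-truth variability and also
makes the aligned-shape covariance full-rank, so a full-mode model can
reproduce arbitrary configurations. Heatmap channels are 128×128 unit
sub-windows centred on the true landmark, rendered as unit-amplitude
Gaussians (σ = 5 px default, configurable) with independent corruptions:
peak shift (direction uniform, distance in a range), spurious secondary
peak, peak attenuation, and clipped additive noise.

What passing tests on these data do **not** show: robustness to correlated
multi-channel failures, anisotropic or multi-modal response shapes beyond
the modelled corruptions, real anatomical shape variation (degenerative
changes, transitional vertebrae), or detector-specific error statistics.
The benchmark isolates the single-outlier regime the correction targets.

## Numerical choices and degenerate inputs

- GPA tolerance 1e-10 / 100 iterations; constraint tolerance 1e-6 / 50
  iterations; early-stop threshold 0.1 px on max displacement.
- Argmax ties break to the smallest row-major index; all-zero channels are
  flagged, positioned at the channel center, and produce zero gradients
  everywhere (no NaNs).
- Similarity fits reject configurations with all source points coincident;
  weights must be nonnegative and not all zero.
- Heatmap stacks are serialized as 22-page 16-bit TIFFs (per-channel
  max-normalized, ×65535) plus a JSON sidecar with the affine metadata;
  quantization error ≤ 1/65535 per pixel. Landmark CSVs round-trip at full
  double precision (17 significant digits).

## Benchmark problem sizes

The end-to-end benchmark (`hasm.benchmark.single_corruption_benchmark`,
also run by `scripts/acceptance.py`) uses 200 training spines and 100
validation stacks with one 20 px peak displacement each — large enough for
stable rates (binomial s.e. ≈ 3% on the improved fraction) while keeping a
full run in seconds on one CPU.

## Known limitations

- Single-resolution search; no per-landmark weighting in the shape step and
  no fusion of multiple shape models.
- The gradient step's proportional law is one reasonable reading of
  "distance and direction from (m_h, o_h)"; alternatives (fixed step along
  o_h) would change the μ scale.
- The slip augmentation is geometric, not biomechanical; it widens the
  shape prior but does not model endplate remodelling or disc collapse.
- Correction quality degrades when many channels fail simultaneously:
  with the majority of heatmaps corrupted the shape prior has no reliable
  anchor.
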