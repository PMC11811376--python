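# hasm — heatmap-based active shape model for lumbar landmark refinement

Automated analysis of lateral lumbar-spine radiographs often starts from 22
anatomical landmarks: the four corners of each vertebral body L1–L5 and the
two endpoints of the S1 upper endplate. Heatmap-regression detectors (CNNs)
localize each landmark as the argmax of a per-landmark response map, but
single-channel failures — occlusion, noise, ambiguous anatomy — can put one
landmark tens of pixels off while the rest are fine. Such outliers dominate
the per-image maximum error and can flip downstream measurements such as
vertebral-slip grading.

`hasm` corrects these failures by combining the detector's own heatmaps with
a statistical shape model of the landmark configuration. It is aimed at
researchers building spine-radiograph analysis pipelines who have per-
landmark heatmaps (or any nonnegative response grids) and want a
detector-agnostic post-processing stage.

## Method

**Shape model.** Training configurations, written as 44-vectors
x = (x₁…x₂₂, y₁…y₂₂), are aligned by generalized Procrustes analysis
(similarity transforms only), projected onto the tangent plane at the unit
mean shape x̄, and decomposed by PCA into modes P with variances λ. Any
configuration is approximated as

    x ≈ T( x̄ + P b ),   |b_k| ≤ 3 √λ_k,

with T a similarity pose. Because spondylolisthesis (vertebral slip) is rare
in training populations, the model would be biased toward normal anatomy;
the training set is therefore augmented with artificial slips: vertebrae
V_start..V_end are rigidly translated by α·β·(UR* − UL*), the top edge of
the first moved vertebra scaled by β ∈ [0, 0.3] and signed by α = ±1.

**Correction loop.** Starting from the per-channel argmaxes, up to 30
iterations alternate:

1. *gradient update* — each landmark moves up its channel's Sobel gradient:
   CLᵢ ← CLᵢ + μ·m_h·(cos o_h, sin o_h), with (m_h, o_h) the bilinearly
   sampled gradient magnitude/orientation and μ the sensitivity (default
   0.02);
2. *shape reorganization* — the configuration is projected onto the first
   n_P = 20 modes of the shape model and mapped back to the image frame.

The loop stops early when no landmark moves more than 0.1 px. An optional
snap-back post-process returns a landmark to its channel argmax when the two
are closer than γ·Ẽ_a, where Ẽ_a is 20% of the mean vertebral-edge length
computed from the detected configuration — trading maximum-error robustness
against mean-error fidelity.

**Metrics.** Point errors E_ij feed per-image maxima/means, their dataset
averages AE_max / AE_mean, scale-normalized NE_max / NE_mean (dividing by
the per-image allowable error E_a,i), an interval histogram over integer
multiples of E_a,i, and paired t-tests between methods.

A synthetic module generates realistic 22-landmark spine populations and
CNN-style corrupted heatmap stacks (shifted peaks, spurious secondary peaks,
attenuation, pixel noise), so the whole pipeline runs offline with no
dataset or trained network.

## Worked example

```python
import numpy as np
from hasm import (HASMConfig, HeatmapNoiseParams, ShapeModel, SpineTemplateParams,
                  correct, generate_dataset, simulate_heatmaps)

# train a shape model on 100 synthetic spines
train = generate_dataset(np.random.default_rng(0), SpineTemplateParams(n_images=100))
model = ShapeModel.fit(train)

# one validation spine whose landmark-10 heatmap peak is shifted 20 px
truth = generate_dataset(np.random.default_rng(1),
                         SpineTemplateParams(n_images=1,
                                             spondylolisthesis_fraction=0.0))[0]
shifted = truth.points[9] + [20.0, 0.0]
stack = simulate_heatmaps(truth, HeatmapNoiseParams(), np.random.default_rng(2),
                          peak_overrides={10: shifted})

result = correct(stack, model, HASMConfig())
print(result.summary())
err0 = np.linalg.norm(result.initial.points - truth.points, axis=1)
err1 = np.linalg.norm(result.landmarks.points - truth.points, axis=1)
print(f"max error: {err0.max():.2f} px -> {err1.max():.2f} px")
print(f"mean error: {err0.mean():.2f} px -> {err1.mean():.2f} px")
```

Output:

```
Heatmap-based active shape model correction
  n_P = 20, mu = 0.02, max_iterations = 30
  iterations run:     2 (early stop)
  landmarks snapped:  0
  mean |corrected - initial|: 2.220 px
  max  |corrected - initial|: 11.187 px
max error: 19.51 px -> 9.15 px
mean error: 1.56 px -> 2.24 px
```

The corrupted landmark's 19.5 px error is halved by pulling it toward the
statistically plausible configuration, at the cost of sub-pixel to few-pixel
displacements of the remaining landmarks away from their (correct) argmaxes
— the characteristic max/mean trade-off of the method.

The same pipeline is scriptable from the shell:

```bash
hasm simulate --seed 5 --out fixture/ --n-train 30 --n-validation 3
hasm build-model --landmarks fixture/train_landmarks.csv --out model.json --augment
hasm correct --heatmaps fixture/stack_000.tiff --sidecar fixture/stack_000.json \
             --model model.json --out corrected.csv
hasm evaluate --detected corrected.csv --truth truth_one.csv --out report.json
```

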