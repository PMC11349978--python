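# gao-kneegrade

Detection and severity grading of knee osteoarthritis (OA) from paired
radiograph views, built around a Gaussian-mutation variant of the Aquila
Optimizer.  The toolkit is aimed at researchers studying
metaheuristic-refined CNN classifiers for musculoskeletal radiographs: it
provides the full processing chain — contrast enhancement, two-view wavelet
fusion, joint-space segmentation, morphological features, a dual-branch CNN
with metaheuristically tuned dense weights, and OA grading — together with a
seeded phantom generator so every stage can be exercised and validated
without clinical data.

## The method

**Gaussian Aquila Optimizer (GAO).** The classic Aquila Optimizer (AQO)
searches a bounded continuous space with four hunting-inspired update rules
(expanded/narrowed exploration, expanded/narrowed exploitation).  GAO
modifies the middle rules with a momentum control factor

    MCF(j) = M0 · exp(1 − j/J) · N_s,     N_s = +1 w.p. 0.6, else −1

whose magnitude decays from `M0·e` to `M0` over the `J` generations, and
adds an elementwise Gaussian mutation of the incumbent best

    S ← S · (1 + exp(−S²))

accepted only on improvement.  Both optimizers are elitist with greedy
per-candidate acceptance, so the best-fitness trace is non-increasing.

**Pipeline.** Each knee is radiographed at two field-of-view angles.  Both
views are enhanced by Adaptive Local Histogram Equalization (per 5×5 tile,
every pixel is multiplied by the CDF value of its intensity bin), fused by a
one-level Daubechies-4 DWT with maximum-singular-value subband weighting,
and binarised/majority-filtered/labelled to locate the joint space — the
dark band between femur and tibia whose width shrinks as OA progresses.
Six morphological features (mean, Pearson kurtosis, skewness, eccentricity,
major/minor axis length) summarise the segmented region and, tiled over the
image, form the Morphological Feature Matrix (MFM).  A dual-branch CNN
(64/128-filter image branch, 32/64-filter MFM branch, three dense layers
4096→2048→2) classifies normal vs OA; GAO then refines the final dense
layer's weights against held-out validation error, seeded with the backprop
solution so refinement can never hurt.  OA-positive images are graded 1–4
by nearest trained pattern over the six features.

## Worked example

```python
import numpy as np
from gao_kneegrade import (
    GAOConfig, gao_optimize, benchmark_objective,
    alhe_enhance, fuse_images, segment_knee_joint, build_mfm,
)
from gao_kneegrade.phantoms import PhantomSpec, generate_phantom

# 1. the optimizer on a 5-d sphere
result = gao_optimize(benchmark_objective("sphere", 5), GAOConfig(seed=1))
print(f"best fitness {result.best_fitness:.2e} after {result.generations_elapsed} generations")
# best fitness 4.08e-08 after 354 generations

# 2. one synthetic knee through the imaging chain
sample = generate_phantom(PhantomSpec(image_size=64, grade=2, seed=5))
fused = fuse_images(alhe_enhance(sample.view1), alhe_enhance(sample.view2))
region = segment_knee_joint(fused)
print(f"joint-space area {region.area} px, pixel accuracy "
      f"{(region.mask == sample.truth_mask).mean():.3f}")
# joint-space area 811 px, pixel accuracy 0.985
```

The first block minimises the 5-d sphere: the run stops once the best
fitness improves by less than 1e-6 over 20 consecutive exploitation
generations (pass `convergence_window=max_iterations` for a full
fixed-budget run).  The second renders a grade-2 phantom (moderate
joint-space narrowing), pushes both views through enhancement and fusion,
and segments the joint space; pixel accuracy is agreement with the
phantom's ground-truth gap mask.

A command-line interface mirrors the library:

```bash
gao-kneegrade simulate --out data/ --n-normal 100 --n-oa 100 --seed 42
gao-kneegrade optimize-benchmark --function rosenbrock --dim 2 --algo gao --seed 1
gao-kneegrade evaluate --data data/ --out report.json
```

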