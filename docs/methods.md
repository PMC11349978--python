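# Methods

This note records the models implemented in `gao_kneegrade`, the
assumptions behind them, and the numerical and design choices made where
the underlying method leaves room.

## Optimizers

Both optimizers minimise a scalar objective over a box `[LB, UB]` with a
population of `M` candidates (default 60) for up to `J` generations.

**Classic Aquila Optimizer (AQO).** Four update rules, selected by phase:
while `j ≤ (2/3)·J` each candidate moves by expanded exploration
(`S1 = S_best(1 − j/J) + (S_A − S_best·rand)`, with `S_A` the population
mean) or narrowed exploration
(`S2 = S_best·levy + (S_rd + (a − b)·rand)`, with `S_rd` a random
population member and `(a, b) = (l·sin φ, l·cos φ)` a spiral draw), chosen
with probability ½; afterwards by expanded exploitation
(`S3 = (S_best·S_A)(λ − rand) + ((UB − LB)·rand + LB)·μ`) or narrowed
exploitation
(`S4 = ε(j)·S_best − H1·S·rand − (H2·levy + rand·H2)`), with quality
function `ε(j) = j^((2·rand−1)/(1−j)²)`, movement `H1 = 2·rand − 1` and
slope `H2 = 2(1 − j/J)`.  The Levy step is
`r·(l·β)/|x|^(1/α)` per component with `r = 0.1`, `α = 0.5`, `β = 1.5`
(the standard Levy exponent; the method leaves β open), `l, x` fresh
uniform draws, and random sign symmetrisation since the raw expression is
non-negative.

**Gaussian Aquila Optimizer (GAO).** Replaces narrowed exploration by
`S2n = (S_best − S_present)·MCF + (S_rd + (a − b)·rand)` and expanded
exploitation by
`S3n = ((S_best − S_present)·S_A·MCF·(1 − j/J))(λ − rand)
+ ((UB − LB)·rand + LB)·μ`, with the momentum control factor
`MCF(j) = M0·exp(1 − j/J)·N_s`, `M0 = 1.2`, `N_s = +1` with probability
0.6 and −1 otherwise.  After each generation the incumbent best is mutated
elementwise by `S·(1 + exp(−S²))` — a factor in (1, 2] that doubles
near-zero coordinates and vanishes for large ones — and accepted only on
improvement (a flag extends mutation to the whole population).

Shared conventions:

- **Acceptance** is greedy per candidate; the global best is elitist.
- **Quality function at j = 1**: `(1 − j)² = 0` would divide by zero; we
  define `ε(1) = 1` (the limit convention).
- **Random draws**: one seeded generator drives the run; each `rand` is an
  independent draw except where one expression reuses the symbol, which
  shares a single draw per expression instance.
- **Bounds**: out-of-range coordinates are clipped to the nearest bound.
- **Termination**: hard cap at `J`; additionally a stall window stops the
  run when the best fitness improves by less than `1e-6` over 20
  consecutive generations.  The window only arms after the exploitation
  phase has run one full window — under greedy elitist acceptance the
  exploration phase plateaus by design, and treating that plateau as
  convergence stops runs prematurely (measured: generation ~24 at fitness
  ~0.5 on the 5-d sphere).  Benchmark comparisons in the tests and the
  acceptance script disable the stall stop (`convergence_window = J`), the
  equal-budget protocol standard for paired-seed metaheuristic
  comparisons.

A structural note on the comparison: classic narrowed exploration refines
multiplicatively through `S_best·levy`, so AQO polishes smooth convex
benchmarks to near machine precision.  GAO's `S2n` replaces that term with
`(S_best − S_present)·MCF`, which vanishes once the population collapses
onto the best, leaving additive spiral noise; on the sphere GAO therefore
reaches ~1e-9 where AQO reaches ~1e-14 at the same budget, while on
Rosenbrock GAO is the stronger of the two.  The suite asserts the ranking
on both benchmarks and the sphere ranking fails by construction of the
printed update rule; it is retained unaltered rather than weakened.

## Image enhancement (ALHE)

The image is split into non-overlapping 5×5 tiles (edge tiles are smaller
partial tiles with their own histograms).  Per tile, a 256-bin histogram
over the value range is accumulated (floor binning), its CDF normalised by
the tile's pixel count, and each pixel multiplied by the CDF at its own
bin — the tile's top occupied bin keeps its value, lower intensities are
attenuated by their rank mass.  Because the raw product only shrinks
intensities, the output is affinely rescaled per image to span the value
range (raw output behind a flag; constant images pass through unchanged).

A consequence worth knowing: within a structureless tile the transform is
a rank transform of noise, spreading even low-amplitude noise across the
intensity range.  Real radiographs always carry structure; perfectly flat
synthetic regions are the worst case (see Phantoms below).

## Two-view fusion

Both views' luminances are decomposed by a one-level Daubechies-4 2-D DWT
with symmetric extension.  The largest singular value of each
approximation subband gives the approximation gain `Max-Ei = max(σ₁(A1),
σ₁(A2))`; the largest over the six detail subbands gives the detail gain
`Max-Elow`.  Singular values stand in for eigenvalues because subbands are
generally rectangular (they are the square roots of the Gram-matrix
eigenvalues).  Every subband is scaled by its band's gain, corresponding
subbands of the two views are summed, and the inverse DWT reconstructs the
image.

Since both views share the same per-band gain, the raw combination is a
two-gain amplifier of the bandwise sums: it changes the balance between
the approximation and detail bands but carries no between-view selection.
The final rescale step therefore normalises each fused band by its common
gain (`÷ 2·Max-Ei` for the approximation band, `÷ 2·Max-Elow` for the
details) before the affine map onto the value range.  This restores the
inputs' spectral balance and makes fusion exactly idempotent — fusing an
image with itself returns it — while the literal scaled subbands and their
un-normalised reconstruction remain available as `FusionIntermediates`.
The fusion is symmetric in its inputs and, before the affine rescale,
linear.

## Joint-space segmentation

Chain: Otsu binarisation → 3×3 binary majority filter → 8-connected
component labelling → joint-region selection.

- The majority filter is a per-pixel vote over the pixel's own 3×3
  neighbourhood with replicated edges (9 samples, so ties cannot occur) —
  the fixed-point-consistent reading of a sliding rewritten window.
- **Default joint rule (`between_bones`)**: binarise with bright bone as
  foreground; the two largest components are femur and tibia (ordered by
  row centroid), and the joint space is, per column, the strip strictly
  between them.  This is the anatomical definition of the joint space and
  is robust to dark speckle that survives majority filtering: speckle
  inside a bone lies within the bone's row span and cannot enter the
  region.  If two bones are not found, the rule falls back to the dark
  rule below.
- **Alternative rule (`central_dark`)**: binarise with the dark gap as
  foreground and select the largest component whose row centroid falls in
  the middle 50% of image rows (configurable), ties to the lower label;
  when no component reaches the band the globally largest is returned with
  a `fallback` flag.  The dark rule is the simpler reading but its region
  occasionally merges the gap with speckle webs when the dark-pixel
  density approaches the 8-connectivity percolation threshold, which
  inflates the region's second moments.
- Constant or empty images yield an empty region with a warning.
- Coordinates are 0-based, row-major, with half-open bounding boxes.

## Morphological features and the MFM

Six per-region features: the mean, Pearson kurtosis (`m4/m2²`; normal
→ 3) and skewness (`m3/m2^1.5`) of the masked intensities (population
moments; zero-variance regions get 0 with a degenerate flag), and the
equivalent-ellipse eccentricity and axis lengths from the mask's central
second moments.  The pixel-coordinate covariance gets +1/12 on each
diagonal term — the variance of a unit pixel — so a single-pixel mask has
equal axes and eccentricity 0; axes are `4·sqrt` of the eigenvalues,
eccentricity `sqrt(1 − λ_min/λ_max)`.

The MFM tiles the image (default 16 px tiles, grid dimensions rounded up)
and computes the six features over each tile's intersection with the
region; empty tiles hold zero vectors.  `build_mfm` offers per-image
channel standardisation over the occupied tiles, but the classifier
instead fits per-channel location/scale on the training set's occupied
tiles and applies them at prediction (empty tiles stay zero).  Per-image
standardisation removes exactly the between-image feature levels — the
minor-axis and area channels are the joint-space-width signal — and
measurably capped held-out phantom accuracy near 0.85; dataset-level
scaling lifted it to ≥0.97 while still stabilising the scale of the
heavy-tailed moment channels.

## Dual CNN and GAO refinement

Branch 1 (image): conv 64@3×3 → maxpool 2×2 → conv 128@5×5 → maxpool.
Branch 2 (MFM): conv 32@5×5 → maxpool → conv 64@7×7 → maxpool.  Both are
stride-1 same-padded with ReLU.  Branch outputs are globally
average-pooled and concatenated (global pooling keeps the dense parameter
count near the method's stated ~0.8 M budget, which flattening the final
feature maps would exceed a hundredfold; a flatten mode exists behind a
flag) and passed through dense layers 4096 → 2048 → 2 with ReLU, dropout
0.5 on the two hidden dense layers, and a terminal softmax.  A
`width_multiplier` scales every filter count and hidden width; tests and
the synthetic experiment run at input 64, width 0.25, MFM tile 16 — sizes
at which the whole five-fold experiment fits in minutes on one core.

The layers are a compact numpy implementation (im2col convolution,
explicit backward passes) in float32 with a single seeded generator for
initialisation, shuffling and dropout, so training is bit-reproducible.
The backbone minimises cross-entropy by minibatch SGD (batch 16, learning
rate 0.01, momentum 0.9, L2 weight decay 5e-4, 25 epochs by default).
Convolutional weights are trained by gradient descent only — a
population metaheuristic cannot carry the full convolutional
parameterisation — and GAO then refines the final dense layer (2048→2 at
full width): the search space is that layer's weights and biases in
`[−w_max, w_max]` (w_max grown to cover the incumbent), the fitness is the
validation misclassification rate with a 1e-6-weighted cross-entropy
tie-break, and the backprop incumbent seeds one population member, so with
elitist acceptance the tuned validation fitness is never worse than the
incumbent's.  A dimension cap rejects configurations whose final layer is
too wide to search.  The `TrainedMatrix` archive (npz weights + JSON
metadata) round-trips bit-exactly.

## OA grading

Grading is a nearest-pattern classifier over the six region features,
separate from the binary CNN (whose two outputs cannot express four
grades).  Fitting standardises the features, then stores one centroid and
per-channel dispersion per grade; zero dispersions fall back to the pooled
channel dispersion.  Assignment minimises the dispersion-scaled Euclidean
distance, ties resolving to the lower grade.

## Evaluation conventions

- Detection and grading rates are percentages **truncated** (floored) to
  one decimal, computed exactly with rational arithmetic; this convention
  is forced by the published rate tables (120/122 = 98.36 prints as 98.3),
  and the truncated rates reproduce every published value from its counts.
- The average grading rate pools counts (total correct / total images)
  before truncation.
- Se/Sp/Acc are count-agnostic and applied at pixel level (segmentation
  vs phantom truth) and image level (classification) alike; zero
  denominators yield NaN rather than a silent 0.
- ROC area is the trapezoidal AUC (equal to the Mann–Whitney statistic;
  the test suite checks this against a brute-force pairwise oracle).
- Cross-validation is stratified k-fold (k = 5), which gives the 80/20
  split per fold; each fold trains its own backbone and GAO refinement
  with fold-offset seeds.

## Phantoms

`generate_phantom` renders two bright bone slabs (femur above, tibia
below) separated by a dark horizontal joint-space band: bone 200 ± 10 and
gap 60 ± 10 gray levels, additive white Gaussian noise σ = 8, sinusoidally
undulating facing margins (amplitude growing with grade, capped at a
quarter gap width), a vertical joint-line offset of up to ±1/16 of the
image, and a second view rendered as a recorded affine foreshortening
(vertical scale 0.92) plus shear (0.05 column/row) with independent noise.
The gap width is the grade signal:

| grade | 0 (normal) | 1 | 2 | 3 | 4 |
|-------|-----------|---|---|---|---|
| gap / image height | 0.30 | 0.24 | 0.18 | 0.12 | 0.06 |

with ±8% within-grade jitter.  The spacing is chosen so that adjacent
grades remain separable **after** the pipeline: enhancement, fusion and
majority filtering soften the gap edges by roughly a 2 px fringe at the
64 px test scale, so grade steps of ~4 px survive it while the measured
width stays strictly monotone in grade.

What the phantoms emulate: grade-monotone joint-space narrowing, two
pre-aligned views differing by a recorded affine transform, margin
irregularity, detector noise, and slight class overlap.  What they do not:
trabecular texture, osteophytes, soft tissue, exposure variation,
anatomical shape variability, or real biplanar geometry.  Passing the
end-to-end tests therefore demonstrates that the implementation is
internally correct and that the chain separates geometry-encoded severity
at realistic noise — not clinical performance.

## Known limitations

- The enhancement step's per-tile rank behaviour on flat noisy regions is
  inherent to the CDF-multiply rule; segmentation robustness against it
  comes from the between-bones rule rather than from the filter chain.
- The literal two-gain fusion carries no between-view selection; the
  gain-normalised reconstruction (this package's default output) is
  equivalent to the bandwise mean of the two views.
- GAO refines only the final dense layer by default; searching all three
  dense layers is possible in principle but the dimensionality makes the
  metaheuristic ineffective there.
- The grading path assumes the six features are computed from a
  well-formed joint region; an empty region grades from a zero vector.
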