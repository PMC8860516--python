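# Methods

This note records the models, parameter choices, and numerical decisions
behind `hsimap`, and what the synthetic-phantom test regime does and does
not establish.

## Speckle model and phantom generator

Coherent imaging produces multiplicative, signal-dependent speckle. We use
the standard fully-developed-speckle model: the observed cube factorizes
exactly as `J = a · n` per band, with `n` drawn i.i.d. from a unit-mean
gamma law of shape `L` ("looks"), so `E[n] = 1` and `Var[n] = 1/L`. `L` is
the single noise dial: `L = 1` is the heaviest speckle, `L → ∞`
(implemented as `speckle_looks=None`) is the noise-free limit. The
generator stores the clean cube, the noise field, and their product, so
the factorization is testable bit-for-bit.

Tissue regions come from one of three geometries: thresholded low-pass
Gaussian random fields (default — contiguous, organic-looking "blobs"
sliced at quantiles so every class holds an equal pixel share), horizontal
stripes, and equal-area nested ellipses. Class spectra are sums of 1–3
Gaussian bumps over wavelength, clipped to [0, 1]; each class's primary
bump is placed at an evenly spaced center across the 400–1300 nm range so
pairwise class means separate by at least `3 × intra_class_sd` at the most
discriminative band — the condition under which clustering at the true k
is well-posed. Bump widths never drop below 1.5× the band spacing, so a
coarse band grid cannot sample past a bump; if the random secondary bumps
ever close the separation gap the generator redraws (seeded, bounded) and
otherwise raises. Pixels scatter around their class mean with i.i.d.
Gaussian noise of `intra_class_sd` (default 0.02 reflectance units),
clipped to [0, 1].

Defaults (64×64 pixels, 128 bands over 400–1300 nm, 3 classes, `L = 4`)
define the study conditions; the acceptance runs use 16 bands for the
clustering experiments, which preserves the spectral separation structure
at a fraction of the cost. The generator emulates region geometry,
spectral separation and multiplicative noise — it does **not** model
camera PSFs, wavelength-correlated noise, illumination gradients,
mixed-tissue (partial-volume) pixels, or anatomical shape priors, so
passing tests demonstrate algorithmic correctness under the stated model,
not clinical performance.

All randomness flows from one integer seed through a single
`numpy.random.Generator`.

## Frost filter

The printed source formulation of the local-window computation is
typographically inconsistent; we implement the classical Frost filter it
describes in prose: for each pixel, weights
`h(k,l) = exp(−K · (σ²/μ²) · d_kl)` over a `(2N+1)²` window, with `μ, σ²`
the window mean and population variance and `d_kl` the Euclidean offset
distance; the output is the normalized weighted sum. Defaults `N = 2`,
`K = 2.0`. Limits: `K → 0` gives the box mean, `K → ∞` the identity;
windows with `μ = 0` output 0. Border handling is edge-repeating
reflection (configurable constant-zero); note scipy's `reflect` and
numpy's `symmetric` name the same convention, and the implementation keeps
the local-statistics pass and the shifted-sum pass on that one convention.
Filtering a cube applies the filter per band; the segmentation stage
consumes the filtered cube. The Lee-style adaptive mean filter
(`s = μ + W(I−μ)`, `W = max(0, 1 − C_n²/C_I²)`) is provided as a baseline.

## Firefly optimizer and cluster-count selection

The optimizer is the canonical double loop: every firefly moves toward
every brighter one by `β₀ e^{−γ r²}(x_j − x_i) + α ε`, `ε ~ U[−0.5, 0.5]`
per dimension, positions clamped to the box, `α` decaying by a
per-generation factor; an elitist record keeps the best-so-far, so the
reported trace is monotone by construction. A lone firefly degenerates to
a bounded random walk (kept alive by the `α` step). Defaults: 25
fireflies, `β₀ = 1`, `γ = 1`, `α = 0.2`, decay 0.97.

For cluster-count selection the search is 1-D over `[kmin, kmax]` (default
[2, 5]); a position is rounded to an integer at evaluation and scored by
the Davies–Bouldin index of a seeded k-means run at that k, memoized per
integer so re-clustering is never repeated. Design choices worth noting:

- **Validity index**: no selection objective is inherent to k-means; we
  chose Davies–Bouldin (minimize) and left the objective pluggable.
- **Lower bound 2**: validity indices are undefined for one cluster, so
  the default box starts at 2 even though the optimizer itself accepts
  any bounds.
- **Stratified initial swarm**: initial positions are evenly spaced over
  the box with seeded jitter rather than i.i.d. uniform. With at most four
  integer candidates and ≥ 4 fireflies this guarantees every candidate is
  scored, making the selection provably equal to exhaustive enumeration of
  the memoized index — the metaheuristic then costs nothing beyond the
  enumeration it cannot beat at this scale, while remaining the generic
  search the pipeline exposes for wider boxes.
- The selection k-means runs with the small-cluster merge disabled so the
  index always scores an exact k-way partition.

## k-means and KNN refinement

Lloyd iterations with the pipeline's stopping rule: stop when the largest
centroid displacement falls below `min_error = 10⁻³` or after
`max_iter = 50` iterations. Nearest-centroid ties go to the lowest
centroid index; an emptied cluster is reseeded to the point farthest from
its former centroid; 5 restarts (seeds `seed + r`) with the lowest final
inertia winning, ties to the lowest restart index. A post-pass merges
clusters below 0.5 % of pixels into their nearest surviving centroid
(disableable). Features are the per-pixel filtered spectra; normalized
spatial coordinates can be appended but are off by default.

KNN refinement is a single-pass majority vote over each pixel's `k_nn`
nearest neighbors — spatial (grid distance; `k_nn = 9` is the 3×3
neighborhood) by default, spectral (feature distance) optionally. Ties
keep the original label, so unanimous regions are fixed points and no new
label can appear.

## Feedforward network

One hidden layer of 16 sigmoid units by default (depth configurable),
sigmoid output, mean-squared error against one-hot targets, plain
(full-batch by default) gradient descent with learning rate 0.5 for 150
epochs. No softmax, momentum or regularization — the point is the plain
sigmoid formulation, verified against central finite differences at
random parameter points (relative error < 10⁻⁵). Training uses a
stratified 80/20 split (250 samples split exactly 200/50); the seed
governs split, initialization and shuffling, making training bit
reproducible. In the synthetic regime the training labels are the phantom
ground truth — the package is explicit that this stage is supervised on
truth, since no independent labelling source exists for phantoms. Cluster
labelling assigns each segmentation cluster its majority predicted class;
per-pixel labelling is available.

## Metrics

PSNR takes the peak value explicitly (1.0 for reflectance, 255 for 8-bit)
and returns `+inf` for identical images. MAE between label maps is
computed after an optimal one-to-one Hungarian matching on the
contingency table, because raw cluster indices are arbitrary under
permutation. Confusion-count metrics are one-vs-rest percentages with the
highest class label as the default positive ("abnormal tissue")
class, macro averages alongside, and `None` — never NaN — for zero
denominators. Pooled accuracy is exact multi-class agreement.

## Pipeline

Stages run in the fixed order simulate → preprocess → filter → segment →
refine → label → evaluate; each is skippable by config, unknown config
keys are rejected by name, and a stage failure halts the run naming the
stage while retaining earlier outputs. The global seed fans out as
`seed + stage_index`, so a stage rerun in isolation reproduces its
in-pipeline behavior. The run manifest records a config hash (paths
excluded), per-stage outputs and the metrics summary; with a fixed seed
two runs are byte-identical.

## Problem sizes

Tests and the acceptance script run on 32–64 pixel square phantoms with
8–16 bands: large enough that class separation, speckle statistics and
validity-index behavior match the full-size setting, small enough that
the whole suite completes in about a minute. The cluster-count
experiments use twenty 64×64×16 phantoms (seeds 0–19 offset by the CLI
seed), 15 fireflies × 10 generations, k-means with 2 restarts.

## Known limitations

- The Davies–Bouldin objective can prefer a merged solution when true
  classes overlap heavily; the k-recovery guarantees hold for the
  generator's separation regime (≥ 3 SD at the best band).
- The Frost filter is O(window² · pixels) per band; large cubes with wide
  windows are slow in pure numpy.
- The network's MSE/sigmoid training plateaus on hard problems; it is
  adequate for the separable-phantom regime, not a general-purpose
  classifier.
- Headline metrics on real in-vivo cubes are out of scope: no deposited
  dataset exists for this pipeline, and the phantom regime cannot stand
  in for one.
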