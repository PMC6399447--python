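# Methods

## Pipeline model

A slide-level label `(predominant, minors)` over the five lung-
adenocarcinoma growth patterns is inferred from independent patch-level
classifications. The model assumes patches are classifiable without
spatial context (each window is scored alone), that non-tissue and
non-neoplastic content is absorbed by the benign class rather than
masked out, and that pattern extent is well approximated by counting
classified windows — the patch-count share of a class stands in for its
area share.

### Sliding-window geometry

Windows are `patch_size × patch_size` squares (default 224), 0-based,
half-open, row-major. Along an extent `E` with stride `s` the window
count is `floor((E − patch)/s) + 1`; the right/bottom remainder is
dropped by default (`edge="keep-last"` re-anchors one final window
flush with the border). "Overlapping by one-fifth" is read as adjacent
windows sharing 1/5 of the patch side: `stride = round(0.8 × patch)`,
i.e. 179 at 224, 45 shared pixel columns. Training extraction instead
chooses a per-class stride: the largest stride in `[1, patch]` whose
total window count over that class's crops reaches the per-class
target, found by integer enumeration (inventories are small; exactness
is worth more than a closed form over heterogeneous crop sizes).
Classes that cannot reach the target even at stride 1 are flagged and
topped up by augmentation.

### Normalization and augmentation

Channel statistics are pooled over every pixel of the raw training
patches, with the population (not sample) standard deviation — at
millions of pixels the distinction is immaterial, so the formula is
simply fixed. Statistics are computed once, before augmentation, and
frozen with the model. Augmentation applies, in order: color jitter
(brightness/contrast/saturation half-ranges 0.2, hue 0.05 cycles —
magnitudes are a design choice, mild enough to respect stain
plausibility), rotation by a uniformly drawn multiple of 90° (a single
fixed 90° rotation adds no diversity; multiples generalize it without
interpolation), and horizontal/vertical flips at probability 0.5 each.
Jitter operates in raw color space; normalization happens at model
input. Every augmented copy is a pure function of `(policy.seed, draw)`.
`expand_dataset` tops classes up round-robin to an exactly uniform
histogram.

### Classifier

The patch classifier is a residual convolutional network implemented
directly in numpy (conv/batch-norm/ReLU residual blocks with projection
shortcuts, global average pooling, linear head), trained with He
initialization, multi-class cross-entropy, and SGD with momentum 0.9.
The learning-rate schedule is `lr(e) = 0.001 × 0.9^e` per 0-based
epoch. The optimizer, batch size (64), and momentum are explicit
configuration, not claims about any reference system. The default
`"tiny"` depth (stem + two residual stages, 8-16-32 channels) pairs
with a 32×32 model input: patches are downscaled before entering the
network, which is appropriate because the synthetic textures are color-
and motif-separable far below full resolution. The standard 18-layer
depth at full resolution is selectable but CPU-expensive. Training is
bit-reproducible under a fixed seed (single-threaded numpy, one RNG for
initialization and batch order).

### Thresholding and aggregation

A patch is assigned only to its argmax class and discarded entirely if
that confidence is below the class threshold (`≥` keeps the boundary);
there is no reassignment to runner-up classes — the most direct reading
of discarding low-confidence predictions. The 5% rule uses as its
denominator the total of *all* surviving patches, benign included,
before any class is dropped (pre-drop basis; `min_fraction` and the
basis are arguments). Ties for predominant go to the lowest canonical
ordinal (lepidic < acinar < papillary < micropapillary < solid) and are
logged; determinism is required and the choice is otherwise arbitrary.
If no cancer class survives, the slide is called benign.

Threshold fitting is a coordinate-wise grid search: classes visited in
canonical order, each threshold optimized over the grid (default
{0, 0.05, …, 0.95}) with the others held fixed, one sweep by default
(`sweeps` repeats until stable). A joint 6-D search would be
exponential in the grid; the per-class sweep matches the structure of
the problem. The objective is the dev-set mean of
`1{predominant match} + Jaccard(minors)`, coupling both label
components; it is pluggable. Benign's threshold is fitted too — it
never appears in labels but modulates the 5% denominator — and can be
pinned at 0. Because the grid contains 0 and sweeps only accept strict
improvements, the fitted set never scores below the all-zeros set.

The probability-averaging baseline takes the mean patch probability
vector; predominant is the argmax over cancer classes, minors are
cancer classes whose mean clears `minor_cutoff` (default 0.05).

### Agreement statistics

Cohen's κ is computed from observed agreement and chance agreement from
marginal frequencies. When both raters are constant the formula is 0/0;
the convention here is κ = 1 if the constant labels agree and 0 if not
(documented, and exercised by per-pattern detection κ when a rare
pattern is absent from every slide). Detection κ binarizes each slide
as pattern-present (predominant *or* minor) vs absent. Per-annotator
summary rows average that annotator's three pairwise values; robust
agreement counts slides where the annotator matches ≥ 2 of the 3
others. Proportion CIs use the normal approximation
`p ± 1.96·sqrt(p(1−p)/n)` (degenerate at p ∈ {0,1}; Clopper–Pearson
available); κ CIs use a percentile bootstrap over slides (default
2,000 resamples, seeded) — also valid for sparse per-pattern κs where
the large-sample variance is unreliable. Metric comparisons use a
two-sample t-test on per-slide 0/1 indicator sequences, the natural
per-slide decomposition of agreement-type metrics; both choices are
recorded configuration, not reconstructions of any particular study's
unstated procedure.

## Synthetic data: what it emulates and what it does not

The generator exists because annotated clinical slide sets are private.
It emulates the *statistical structure* the pipeline depends on:
multi-region slides with known per-class area fractions, variable-size
single-class training crops (lognormal dimensions calibrated to median
429×473 / mean 718×771 pixels), patch predictions with controllable
confusion and confidence, and multi-annotator label sets with planted
disagreement.

Slides are seeded-Voronoi mosaics: ~24 cells per present class,
assembled on a 4-pixel-block grid, walked in random order against
per-class pixel quotas (the quota-crossing cell is split along x), so
realized area fractions match the request to single-pixel rounding —
well inside the 2-percentage-point recovery tolerance. Region
boundaries are the only mixed-texture patches; ground-truth slide
labels are derived from realized pixel fractions with the *same*
5%/benign-drop rule used at inference, which makes end-to-end recovery
well-posed. Textures are parametric (base color + motif + Gaussian
noise), chosen so a nearest-centroid mean-color classifier exceeds 95%
patch accuracy: the classification task is deliberately easy. Passing
tests therefore demonstrate that the pipeline's *mechanics* (geometry,
normalization, training loop, thresholding, aggregation, statistics)
are correct — not that the tiny network would separate real H&E
histology, which exhibits stain variation, scanner artifacts,
intra-class morphological diversity, and gigapixel scale that the
generator does not model.

Prediction tables draw each patch's true class i.i.d. from the
composition, the predicted class from a row-stochastic confusion
matrix, and the winning confidence from
`Beta(mean·strength, (1−mean)·strength)` clipped to `[0.35, 1]`, with
the residual mass Dirichlet-split over the other classes (uniform
fallback preserves the argmax contract). Planted annotation sets give
annotator *j* a disjoint flip set of `round(r_j · n)` slides whose
predominant label is shifted deterministically, making every pairwise
agreement exactly `1 − r_i − r_j`.

`random_composition` keeps every included cancer fraction ≥ 7.5% with
consecutive fractions ≥ 7.5% apart and benign ≥ 5%, so neither the 5%
boundary nor the predominant ordering can be flipped by sampling noise
in downstream recovery checks.

## Problem sizes and numerical choices

Default desk-scale conditions, chosen once: synthetic slides
2048×2048 (121 windows at the default overlap); end-to-end trained
runs use 1536×1536 held-out slides (an 8×8 window grid), 200 training
patches per class from 6 crops per class, the tiny depth at 32×32
input, 6 epochs, and 2,000-patch prediction tables for the error-free
recovery check. Tolerances: probability vectors sum to 1 within 1e-6
(softmax in float64); the normalization fixed point is checked at 1e-6;
κ against its oracle at 1e-12. Degenerate inputs fail loudly: empty
prediction lists, zero-total distributions, constant channels,
non-stochastic confusion rows, undersized slides (the deficient
dimension is named) — except undersized *crops*, which are skipped with
a warning because real crop inventories routinely contain a few.

## Known limitations

- Textures are not histology; no stain normalization (Macenko/
  Reinhard), no pyramidal multi-resolution handling, no elastic
  deformation.
- Aggregation is spatially blind by design; no neighborhood smoothing
  or segmentation.
- The numpy network is single-threaded and CPU-bound; the 18-layer
  depth at 224×224 input is functional but slow, and pretrained-weight
  import is out of scope.
- Absolute patch counts per slide are far below clinical scans
  (dozens, not thousands); only the overlap geometry is emulated.
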