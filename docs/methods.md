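# Methods

This note documents the models and procedures implemented in
`birads_cad`, the parameters that matter, the numerical conventions, and
the design choices made where the underlying descriptions left the
design open.

## Segmentation model

A mass is assumed hyperintense relative to its surrounding tissue, so
the region-growing homogeneity criterion is *grey level ≥ threshold*
with 8-connectivity, seeded at the ROI center pixel. Because the
predicate is monotone in the threshold, the candidate masks grown at
increasing thresholds are nested, which the test suite asserts as an
invariant. Candidate thresholds are `n_thresholds` (default 16) values
evenly spaced over the ROI's [min, max] grey range; a single requested
threshold uses the midpoint. The original protocol has an expert
radiologist pick and refine the final contour; that step is replaced by
an automatic proxy — the candidate whose equivalent-circle radius
`sqrt(area/π)` is closest to the lesion radius reported with the case,
ties toward the larger mask — plus an interactive hook for a human
chooser. No contour-refinement operator is implemented, since no
refinement rule is specified anywhere.

Interior holes are filled before boundary extraction so the contour is
a single closed loop. Boundary tracing is Moore-neighbour tracing,
clockwise in screen convention, starting from the topmost-leftmost
pixel (whose west neighbour is provably outside the mask and therefore
a valid initial backtrack). The walk terminates when it is about to
repeat its first transition; because the next state is a deterministic
function of (pixel entered, direction of entry), this closes the cycle
exactly, including on single-pixel-wide spurs where boundary pixels are
legitimately revisited.

## Feature definitions and conventions

Throughout, moments use the population convention (divide by n),
skewness is `m3/m2^1.5`, kurtosis is the non-excess `m4/m2²`, and
zero-variance inputs report skewness and kurtosis of 0. All entropies
are Shannon entropies in bits. The seven summary statistics are always
(mean, max, min, std, variance, skewness, kurtosis).

**Shape (ids 1–9).** The contour is resampled at 128
arc-length-uniform points. Continuity is the mean squared deviation of
consecutive-point spacing from its mean; curvature the mean squared
norm of the discrete second difference; irregularity the count of
resampled points whose turning angle exceeds τ = π/12. Before the
turning angles are measured, the resampled boundary is smoothed with a
short circular moving average (window `n_points/32`, i.e. 4 samples at
the default): at ~1 px sample spacing a rasterized smooth curve
staircases through ±45° steps, and without the smoothing the
irregularity count measures pixelation rather than lesion geometry (a
perfect digital disc scored ~68/128; with the smoothing it scores 0 and
grows monotonically with boundary perturbation amplitude). The
difference area is the number of pixel centers inside the convex hull
of the mask's pixel centers minus the mask pixel count, computed with
exact half-space tests; it is exactly 0 for digitized convex regions.
The variation function is the Feret diameter at 180 directions over
[0, π), computed from convex-hull vertices (the pairwise maximum
projection is attained there); its entropy normalizes the extent
sequence to sum 1.

**Margin (ids 12–32).** 32 waveforms of 64 samples at 1 px spacing are
taken along centroid-to-anchor directions, anchors being the contour
points angularly closest to rays every π/16; sample 32 (0-based) lies
on the anchor, 32 samples inside, 32 outside; out-of-image samples
clamp to the nearest border value (bilinear interpolation otherwise).
The edge probability vector is the absolute first difference of the
3-sample-moving-average-smoothed profile, zero-padded at the inner end
to keep length 64 and normalized to sum 1 (exact to 1e-9). A constant
profile yields the uniform vector. The index of the maximum is signed
relative to the margin (positive outside), with the argmax computed on
the vector rounded to 9 decimals so that theoretically tied maxima (a
step spread across the smoothing window) tie-break by position rather
than by floating-point noise — this also makes the margin features
exactly invariant under image-wide additive grey shifts. The wavelet
construction referenced by the original margin-feature description is
not publicly specified; the normalized smoothed gradient magnitude is
this package's own operationalization of "edge evidence per position"
and has clean analytic test cases (step, ramp, constant).

**Density (ids 33–130).** The ROI is min–max quantized to 64 grey
levels. Co-occurrence matrices are accumulated symmetrically at the 8
angles {0, π/8, …, 7π/8} with integer displacement
(round(d·sin α), round(d·cos α)), and normalized to sum 1. Two textual
ambiguities were resolved as follows: the distance set is all integers
1..⌊L/2⌋ (L = ROI side) — a d of 0 is degenerate and the 7-statistics
summary requires a distance axis — and the 14 descriptors are averaged
over the 8 angles per distance before the statistics are taken over
distances, which is the only reading that yields exactly 14 × 7 = 98
values. The GLCM is computed over the full square ROI, not restricted
to the mask, since the density descriptors are defined for the ROI
window. The 14 Haralick descriptors use base-2 logarithms everywhere;
the information measures use HXY1/HXY2 with the same base, and the
maximal correlation coefficient is the square root of the
second-largest eigenvalue of the Q matrix after dropping zero-marginal
grey levels. Degenerate marginals report correlation and MCC of 0.

## Normalization and splitting

Min–max scaling is fitted on the training split only and applied with
clamping to [0, 1] elsewhere; a constant training feature maps to 0.
This avoids test-set leakage and out-of-range inputs at the cost of
saturating genuinely novel test values. The evaluation split is
stratified 60/40 (125 cases per class give exactly 75/50).

## Genetic feature selection

Chromosomes are fixed-length sequences of distinct feature ids 1..F.
Populations have size 4·`population_base`; elitism count is fixed at 2;
crossover probability is 1; mutation probability is P_m = 0.01 per
gene. Crossover uses L−1 points — genes alternate between the parents
positionally — and mutation first replaces every repeated id with a
random absent one (guided repair), then applies random resetting at
P_m. Fitness values are cached per subset (order-insensitive), so a
converged population costs almost nothing to iterate further.

Two design choices deserve emphasis:

* **Parents are re-shuffled before crossover.** A chromosome encodes an
  unordered subset, but strict positional alternation makes ids compete
  for fixed slots: two useful genes stuck at the same position in
  different chromosomes can never be combined into one child, and
  populations were observed to converge with complementary genes
  trapped at one parity. Randomly permuting each parent's gene order
  before the positional exchange removes this pathology while leaving
  the crossover operator itself unchanged.
* **Cross-validated fitness.** The subset fitness is the mean accuracy
  of a stratified 3-fold rotation within the training table (never the
  held-out test set). A single 75/25 validation split was implemented
  first and found to make selection a lottery over validation noise:
  supersets of a good subset routinely beat it by one lucky validation
  case. The 3-fold average exposes the real cost of a noise feature;
  single-split behaviour remains available via `cv_folds=None`.

The sweep solves L = 1 exhaustively, L = F with a single evaluation,
and intermediate sizes with the GA under a schedule that shrinks slowly
with L (default population `max(20, 4⌈(F−L+4)/4⌉)`, generations
`max(15, 60 − L/3)`, stagnation stop after 10 unimproved generations,
all overridable). Global-best ties break toward fewer features, which
matters in practice: a superset of the optimum often ties it to within
estimate resolution.

## Classifier

One hidden layer of `H = min(⌊4 + 0.75·I⌋, 2I−1)` logistic units
(H = 1, 38, 101 for I = 1, 46, 130), softmax output over the four
categories, cross-entropy loss; training uses scikit-learn's
`MLPClassifier` behind the module surface. Defaults: adam, learning
rate 0.01, up to 500 epochs, patience 25, deterministic under a seed.
For GA fitness the L-BFGS solver with a small iteration cap is the
default configuration — on the few-feature, few-hundred-case fits the
wrapper search performs in bulk, it converges in milliseconds and is
exactly reproducible.

## Synthetic fixtures

A phantom is a star-convex lesion on a 60-grey background: boundary
radius `R + Σ aₖ cos(kφ + φₖ)` (total amplitude split across
harmonics, phases seeded), interior brightened by the contrast, edge
blurred by a Gaussian, plus additive Gaussian noise (σ = 3 by default).
The category archetypes order the axes monotonically — B2: amplitude
0 px, blur 0.5 px, contrast 110; B3: 1.5/1.0/95; B4: 3/2/80; B5:
5/3/65 — mirroring how BI-RADS descriptors run from least to most
suspicious; synthetic ages drift upward with category (means 46/53/
60/67, σ 8). Phantoms emulate the three descriptor axes with known
ground truth; they do **not** model fibroglandular texture, overlapping
structures, pectoral muscle, acquisition artifacts, or the correlation
structure of real mammograms, so passing tests demonstrate that the
pipeline measures what it claims on controlled geometry, not clinical
performance.

Synthetic feature tables plant informative columns as class-shifted
unit-variance Gaussians: the mean for class k (B2..B5 → 0..3) is
`effect_size · k`, i.e. a standardized separation of `effect_size`
between adjacent categories, matching the ordinal drift of BI-RADS
descriptors; all other columns are class-independent standard normal
noise. An earlier design gave each informative feature a distinct
binary class pattern, but pairs of such patterns can jointly encode all
four classes (making the third feature redundant) and individually
weak patterns let informative ids go extinct under
fitness-proportional selection; the ordinal design makes each planted
feature individually salient and the planted set jointly optimal.

## Problem sizes used by the test suite

The recovery experiment uses five tables of 400 cases (100 per class),
subset sizes 1–4, and a reduced GA schedule (populations 24–32,
generations 10–100 shrinking with L); at this size the 3-fold fitness
resolves the planted triple's true advantage over its supersets, and
the five seeded sweeps finish in under ten minutes on one core. The
end-to-end run uses 120 phantoms of radius ~16 px; GA-vs-enumeration
equivalence uses a deterministic 10-feature landscape with additive
weights plus pairwise synergies.

## Known limitations

* The automatic candidate selection depends on a reasonably accurate
  reported lesion radius; a poor estimate selects an under- or
  over-grown mask.
* Region growing assumes a bright lesion on a darker background and a
  seed inside the mass; ring-enhancing or hypointense lesions violate
  the model.
* The margin edge-probability vector is a gradient surrogate, not a
  reproduction of the original wavelet construction; absolute feature
  values are not comparable across implementations, only their
  ordering behaviour is contractual.
* Published headline results on real screening data (e.g. 84.5%
  four-class accuracy on 500 DDSM masses) require the original images
  and radiologist-guided segmentation and are out of scope; what is
  reproduced exactly is every metric derivable from the published
  confusion matrix, plus the sizing rule's printed examples.
* The GA is stochastic; with small schedules it can return a
  near-optimal subset rather than the optimum. The acceptance suite
  therefore asserts recovery in ≥ 4 of 5 seeded runs, not in every run.
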