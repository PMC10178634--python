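# Methods

`mammocad` implements a computer-aided-diagnosis (CAD) processing chain for
mammography image classification. The chain has six stages — class-balancing
augmentation, hybrid contrast enhancement, feature extraction, serial
mid-value fusion, flower-pollination-controlled regula-falsi (FPcRF) feature
selection, and a cross-validated evaluation harness — each usable on its own.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic fixtures do and do not show.

## Contrast enhancement

An RGB raster is reduced to grayscale with BT.601 luma weights
(0.299, 0.587, 0.114); 2-D inputs pass through. The enhancement is two
deterministic stages.

**Histogram remapping.** With `L` gray levels (default 256), the empirical
pdf `p(k) = h_k / h` and cdf `c(k)` are computed by flooring real-valued
pixels to integer levels. Each pixel at level `k` maps to

    F(k) = lo + (hi - lo) * c(k)

By default `lo`/`hi` are the *observed* minimum and maximum intensities, not
0 and L−1: mammograms are often already intensity-windowed, and anchoring to
the observed range preserves that windowing. A `fixed_range` flag restores
the full-range convention. A constant image is returned unchanged — the map
is ill-posed when the range collapses.

**Local contrast stretch.** With local mean `mu` and standard deviation
`sigma` over an odd square window (default 7×7, reflect padding at borders)
and global mean `gm` of F:

    G = Q * (F - c*mu) + mu^a,      Q = K * gm / (sigma + beta)

Defaults `K = 0.8`, `beta = 1.0`, `c = 1.0`, `a = 1.0`. The gains `c` and
`a` have no canonical published values; with `c = a = 1` the transform
reduces to classical adaptive contrast enhancement (amplify the deviation
from the local mean, add the local mean back), which is the safest reading
of the ambiguous `c×mu + mu a` term. The trailing local-mean term is read as
the exponentiation `mu^a`; a `mean_term="linear"` option selects the
multiplicative reading `mu*a` instead. `beta > 0` keeps Q finite on flat
regions. Output is clipped to `[0, L-1]`; no range-handling convention is
published, and clipping is the conservative choice.

*Numerical note.* The stretch is evaluated in residual form
`G = F + (Q-1)*(F - c*mu) + (mu^a - c*mu)`, which is algebraically identical
but makes the identity limit (Q=1, c=1, a=1 ⇒ G=F) exact in floating point
rather than merely close.

## Class-balancing augmentation

Three geometric operations are used: horizontal flip, vertical flip, and 90°
counter-clockwise rotation. These generate the dihedral group of the square,
so only 7 distinct non-identity transforms exist per source image. Chains
are enumerated by round (round r = all length-r chains in lexicographic
operation order, skipping chains that equal an earlier transform); the three
rounds contain 3, 3, and 1 chains. Once exhausted the rounds cycle again —
necessary because published targets can exceed an 8× multiplier (e.g.
557 → 6000), which *no* purely geometric scheme can reach without repeats.

Targets are met **exactly** (reach-then-truncate): full rounds are taken
whole, and the final partial round is truncated with a seeded shuffle.
Within each chain, every source image is used once before any is reused.
The train/test split is stratified per class, seeded, with training
receiving the floor of `ratio * n` — an arbitrary but documented rounding
rule. Whether to augment before or after splitting is the caller's choice of
call order; the bookkeeping examples augment first, which reproduces exact
3000/3000-style splits.

## Feature extraction contract

Downstream stages depend only on the `FeatureMatrix` contract: N×d finite
real matrix, per-row labels, provenance (backbone id, original vs enhanced
source). Production features are expected from a CNN's global-average-pooling
layer (d = 2048 for ResNet50); fine-tuning and any training loop are out of
scope here, since every downstream stage is distribution-agnostic. The
bundled *toy backbone* — bilinear resize to 32×32, flatten, fixed seeded
Gaussian projection scaled by 1/√n_in, tanh — is a deterministic,
bit-reproducible stand-in with no bias term (the zero image maps to the zero
row). It exists for testing, not as an approximation of CNN features.

## Serial mid-value fusion

The original-image and enhanced-image matrices are concatenated column-wise
(d = d1 + d2; rows and labels must align). Each column is summarized by a
scalar score — mean activation by default, max and median selectable; the
per-feature statistic is not pinned down by any published definition, and
the mean is the conventional column summary. The cutoff is the mid-value

    Fnc = (min(scores) + max(scores)) / 2

and columns with `score >= Fnc` are kept (boundary inclusive). The
maximum-score column always qualifies, so the retained set is never empty.
Retained indices, scores and the threshold are recorded for provenance.

## FPcRF feature selection

A wrapper selector: candidate feature subsets are scored by the stratified
k-fold (default 5) cross-validated misclassification rate of a 1-nearest-
neighbor classifier (Euclidean), the "fine KNN" preset. Fold assignment is
seeded, so fitness is a deterministic function of the mask.

**Search.** n pollens (default 20) hold continuous positions in `[0,1]^d`.
Per iteration, each pollen moves by global pollination with probability
p = 0.8 — a Lévy-flight step `y + theta*L(lambda)*(y - B)` toward/away from
the global best B — otherwise by local pollination
`y + mu*(y_z - y_k)`, mu ~ U(0,1), with two distinct other members.
Positions are clipped to `[0,1]`. The `(y - B)` orientation follows the
printed recurrence of the source method; the textbook flower-pollination
algorithm uses `(B - y)`, available via `canonical_fpa=True`. Defaults
theta = 0.01 and lambda = 1.5 are standard FPA practice. Lévy steps use the
Mantegna algorithm, whose output has the correct stable tail
`P(|s|>x) ~ x^-lambda`; the tail index is what matters for occasional long
jumps, and it is verified empirically by a Hill estimator in the tests.

**Encoding.** Positions map to masks by thresholding at tau0 = 0.5
(coordinate selected iff ≥ tau0); an all-empty mask falls back to the single
largest coordinate. Moves are accepted greedily (only if strictly better for
that pollen), making the best-so-far trace non-increasing by construction.
The algorithm always runs all `max_iter` iterations (default 50) — no early
stopping. Ties between equal-fitness masks prefer fewer features, then the
lexicographically smaller index set.

**Regula-falsi refinement.** After the loop, the binarization threshold
itself is refined. Over the bracket `[min(B), max(B)]` define
`g(tau) = fitness(mask(tau)) - fitness(mask(tau0))`. An 11-point scan looks
for a sign change; if found, the false-position iteration

    V = (r1*g(r2) - r2*g(r1)) / (g(r2) - g(r1))

localizes the root Vn (tolerance 1e-4 on |g|, 50 iterations max, iterates
always inside the bracket). With no sign change, Vn is the scan-grid argmin.
If the refined mask is worse than the tau0 mask, Vn falls back to tau0 — the
refinement never degrades fitness. A constant best vector degenerates to
Vn = tau0. Rooting the fitness-difference of the threshold is a design
choice: it is the reading under which a root-finding step on the converged
best vector is executable at all, and the argmin fallback keeps it safe when
the fitness landscape never recrosses the tau0 level.

Fitness values are cached per mask within a run (binarized positions repeat
often), and the 1-NN CV error is computed from a single pairwise-distance
matrix with same-fold neighbors masked out — numerically identical to
fitting a 1-NN per fold, and cross-checked against scikit-learn in the
tests.

## Evaluation harness

Final classification uses stratified k-fold CV (default 10) with out-of-fold
predictions pooled into one confusion matrix. The classifier registry maps
common MATLAB Classification Learner preset names onto scikit-learn
estimators: linear/quadratic/cubic polynomial and RBF SVMs, 1-NN, and
feed-forward networks of widths 10/25/100 and depths 1–3. Exact preset
parity with MATLAB is explicitly not promised.

From the confusion matrix: accuracy = trace/total; precision, sensitivity,
F1 and FPR are computed per class (one-vs-rest) and macro-averaged — the
averaging rule for multi-class tables is not published, and macro is the
symmetric default; Cohen's kappa `(po - pe)/(1 - pe)`; multi-class MCC in
its generalized-correlation (R_k) form. All reported in percent except FPR
(fraction). Zero-denominator classes contribute 0 and set a warning flag.
Wall time is recorded but never asserted — it is hardware-dependent, and the
end-to-end pipeline report omits it entirely so that seeded runs are
byte-identical.

The margin of error of a set of metric values is
`mean ± z * s / sqrt(n)` with s the ddof-1 sample standard deviation and
z = 1.0 at 68.3% confidence, 1.960 at 95% (other levels via the normal
quantile). For the pair {77.13, 86.63} this gives center 81.88; a published
analysis of the same pair prints a center of 82.88 with half-widths that do
not follow from any recoverable formula, so this package implements the
standard formula and documents the discrepancy rather than matching the
printed value.

## Synthetic fixtures

**Images.** A noisy constant background (default level 60, noise σ = 5 on a
0–255 scale) with one bright plateau blob per lesion image: intensity
`background + contrast` (default contrast 60) inside a random-radius disk,
Gaussian falloff outside; the "malignant" class adds angular spikes at the
rim, the "normal" class has no blob. Lesion masks are recorded. This gives
the enhancement stage the right *shape* of input (low contrast, bright
compact lesion) but mimics no real mammogram statistics — no tissue texture,
no pectoral muscle, no acquisition artifacts — so passing tests demonstrate
algorithmic correctness, not clinical performance.

**Feature matrices.** Informative columns are Gaussian with class-dependent
means separated by `effect_size` within-class standard deviations; noise
columns are standard Gaussian, independent of class; planted column
positions are seeded-random and recorded as ground truth. The recovery
benchmark (defaults: 2 classes × 200 samples, 5 informative of 50 columns,
effect size 2) runs the selector across seeds and reports planted-column
recall, precision, selected-set size, and CV-error improvement over the
all-features baseline. Real GAP features are correlated and non-Gaussian;
the selector's contract is distribution-agnostic, so the Gaussian design is
chosen for analyzability, not realism.

## Problem sizes used in the checks

The bundled checks run at desk scale by design: enhancement oracles on 5×5
images, fusion brute force on ≤ 10×16 matrices, selector recovery at
d = 50 / 400 samples / 10 seeds, exhaustive subset enumeration at d = 10
(1023 subsets, 5 seeds, 30 samples/class), and the end-to-end pipeline on
18 synthetic 64×64 images with a 32-dimensional toy backbone. Augmentation
bookkeeping runs at the full published counts (they are cheap — planning is
O(target)).

## Known limitations

- No fine-tuning/training of deep backbones; feature quality is the
  caller's responsibility. The toy backbone is a test vehicle only.
- The per-feature fusion statistic and the continuous-to-mask encoding are
  documented design choices where no published definition exists; both are
  surfaced in configuration and provenance.
- The selector's fitness is a full CV per candidate mask: cost grows as
  O(n_pollens · max_iter · N²) — fine to a few thousand samples, not beyond.
- Macro-averaged FPR on heavily imbalanced multi-class data can look
  optimistic; per-class rates are available from the confusion matrix.
- `margin_of_error` assumes approximately normal sampling of the metric
  values handed to it; with n = 2 values it is a formality, not inference.
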