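# Methods

`ctexture` implements a windowed texture-analysis pipeline for detecting
abnormal bowel-wall attenuation patterns — white, gray, water-halo sign,
fat-halo sign and black, plus ischemia, benign and control appearances — in
grayscale CT slices. This note records the model, the numerical choices, and
what the synthetic test bed does and does not establish.

## Feature model

Each rectangular window is summarized by six descriptors of its gray-level
content:

1. **Mean** m = (1/N) Σ xᵢ and **population variance**
   σ² = (1/N) Σ (xᵢ − m)², both with divisor N (no sample-size correction;
   windows have thousands of pixels and the population convention keeps the
   estimators consistent with the shape coefficients below).
2. **Skewness** g₁ = (1/N) Σ ((xᵢ − m)/σ)³ and **excess kurtosis**
   g₂ = (1/N) Σ ((xᵢ − m)/σ)⁴ − 3. The excess convention is deliberate: a
   normal gray-level distribution scores 0 for both shape coefficients,
   which is the reference point the rest of the pipeline assumes. Raw
   (non-excess) kurtosis is kept in the feature vector's debug payload.
   Both are undefined for a constant window; `extract_features` records 0
   and sets a `degenerate` flag instead of aborting a whole-image scan, and
   the ROI search never matches a degenerate window.
3. **Co-occurrence entropy.** Intensities are uniformly binned from the
   image bit range to L quantized levels (default **L = 32**; a 256² matrix
   is badly under-populated by the ~50×50-pixel windows the classes are
   trained on, while 32² ≈ 1000 cells against ~2500 pixel pairs is
   informative and stable). The gray-level co-occurrence matrix counts
   *ordered* pixel pairs at displacement (d_r, d_c) = (+1, +1) — one pixel
   right, one down, rows increasing downward — with no transpose
   symmetrization. Entropy is H = −Σ a_pq ln a_pq in **nats** (0·ln 0 = 0);
   the log base is configurable but natural log is the default.
4. **Box-counting fractal dimension.** The window is binarized at its mean
   intensity (Otsu and fixed-threshold rules are available) and the
   foreground mask is covered by r×r grid boxes anchored at the window
   origin for the dyadic ladder r = 1, 2, 4, … up to half the shorter side.
   d_B is minus the least-squares slope of log n(r) against log r. No
   grid-offset minimization is attempted: the "minimum number of boxes" is
   operationalized as the origin-anchored count, which is the standard
   estimator and keeps the feature deterministic. Degenerate masks (all
   foreground / all background after thresholding) short-circuit to 2 / 0.

Features are z-scored (f* = (f − μ_f)/σ_f) with μ_f, σ_f estimated on the
**training half only**; a zero-spread feature maps to 0 with a warning.

## Classification

Per-window classification is a k-nearest-neighbor majority vote (default
k = 3) under the Euclidean distance between z-scored feature vectors. Vote
ties are broken by the smallest mean distance among the tied classes, then
by vocabulary order, making predictions deterministic and independent of
training-set ordering; distance ties at the k-th neighbor are resolved by
including all tied neighbors in the vote.

Group-level assignment uses the Bhattacharyya distance between Gaussian
class models (mean vector mᵢ, covariance Cᵢ):

D_B = ⅛ (mᵢ−mⱼ)ᵀ [(Cᵢ+Cⱼ)/2]⁻¹ (mᵢ−mⱼ) + ½ ln( |(Cᵢ+Cⱼ)/2| / √(|Cᵢ||Cⱼ|) )

A query *collection* of windows is fitted with its own mean and covariance
and assigned to the trained class at minimum D_B
(`separability_classify`). The two routes are intentionally distinct: the
Euclidean k-NN yields per-pattern confusion matrices; the Bhattacharyya
rule compares whole sample populations (ischemia vs benign vs control),
which is how a screening decision over a patient's full set of windows
would be made. We do not run per-sample k-NN under Bhattacharyya — a
between-distribution distance has no meaning for a single vector.

Covariances are ridge-regularized (ε = 10⁻⁶ · trace/dim on the diagonal)
**only when near-singular** (smallest eigenvalue ≤ 10⁻¹⁰ of the largest).
Six features can exceed a small class's sample count, where the ridge keeps
the distance finite; well-posed models keep their exact closed-form values.

The benign class is trained as two sub-patterns (`benign_gray`,
`benign_control_like`, with separate trained window sizes) and merged into
a single "benign" row/column in every confusion matrix.

## Region-of-interest search

The forward search scans the image with a window of the **average trained
pattern size** — (50, 55) pixels for the nine shipped classes — from the
top-left corner, left-to-right and top-to-bottom, with a stride of one full
window (configurable down to 1 px). Each window's feature vector is scored
against every trained pattern by the symmetric relative error

e(a, b) = |a − b| / max(|a|, |b|) × 100,

averaged over the six features (max-aggregation available); for two values
of the same sign this is exactly (1 − F̂/F)·100 with F the larger value.
A window whose best score is within the threshold (default **20%**) is
retained and spawns same-size candidate windows to its right, below and
diagonal, each re-scored independently, recursing to depth 3. Retained
windows are deduplicated; overlapping same-class windows can be merged to
union bounding boxes for reporting.

Two deliberate choices here:

- **Scoring uses raw (unnormalized) features.** The relative error is
  scale-free per feature, so z-scoring adds no invariance — and it actively
  breaks the measure: z-scores cross zero, where a ratio-based error
  saturates near 100% regardless of how close the values are. On the
  synthetic classes, within-class best scores run 1–18% on raw features
  versus 18–34% on z-scores, with off-class background at 33–43% raw. The
  z-scored Euclidean distance to the best pattern is recorded in each
  detection as a diagnostic.
- **Expansion spawns neighbors rather than growing the window**, matching
  the window-quantized motion of the primary scan; in-place growth is
  available behind `SearchConfig(expand="grow")`.

The 20% threshold is a package default, surfaced prominently in
`SearchConfig`; zero false detections on pattern-free phantoms are already
reached at 5%.

## Evaluation harness

Stratified random splits at 50/50, 60/40 or 70/30 (per-class rounding, at
least one sample on each side) or leave-one-out; normalization is refitted
per fold on the training half. Confusion matrices are reported as
row-normalized proportions over the eight reporting classes in the order
white, gray, water_halo, fat_halo, black, ischemia, benign, control.

Sensitivity is the **unweighted mean over diseased-class rows** (the five
attenuation patterns plus ischemia) of the proportion mass falling in
diseased-class columns, ×100, rounded half-up to integer percent;
specificity is the same construction over the benign and control rows.
This diseased/non-diseased partition and the unweighted row average are the
only aggregation that reproduces the reference sensitivity values
(98/98/98/82%) carried in the packaged tables `t1`–`t4`; a sample-weighted
pooled variant is available behind a flag. Applied to the same tables, the
textbook specificity definition yields 41/40/42/44% — **not** the 59/60/58/56%
printed alongside them in the source material, and no aggregation we tested
reproduces those figures (nor the flat 50% quoted for the three group-level
tables, whose benign diagonals read 0.23/0.25/0.57). The package reports
the textbook definition and leaves the discrepancy documented rather than
reverse-engineered.

## Synthetic study conditions

No public dataset exists for these pattern classes, so the test bed is
statistical emulation, shipped as a versioned preset file
(`data/class_presets.json`) with one recipe per class: target mean and
variance of the gray-level histogram, skew direction (a shifted-exponential
tail), a correlation length (Gaussian smoothing, which lowers co-occurrence
entropy), a roughness mix (which raises the thresholded texture's box
dimension), and for the two halo signs three concentric rectangular bands
with a dark middle layer. The structured field is standardized to the
target mean/variance before integer rounding, so sample moments land within
2% / 10% of target for windows ≥ 64×64. Per-class trained window sizes
(55×59 white … 51×55 control) follow the sizes the patterns were defined
at. `generate_training_set` can add per-sample jitter of the target mean
and log-variance to emulate the within-class spread of real windows; the
class-separation dial (`make_separated_classes`) scales all between-class
parameter contrasts jointly and uses that jitter, and downstream k-NN
accuracy is monotone in the dial.

Phantoms embed non-overlapping class patches into a deliberately
out-of-vocabulary background (mean 128, variance 3000 — far from every
trained class in the variance and entropy features). The search-recall
suite embeds patches of the seven *stationary* classes at twice the scan
window size, which guarantees — at the default full-window stride — that at
least one scan-grid cell lies entirely inside the patch regardless of
placement; a recall hit is a detection window with ≥ 50% of its area inside
the truth patch. Halo patches are excluded from embedding: their banding is
rendered at patch scale, so no window-sized sub-view of an oversized patch
reproduces the trained full-ring statistics — a structural property of
non-stationary patterns, not of the detector. Halo classes remain in
training and in all classification experiments.

What passing these suites shows: the feature extractors hit their analytic
oracles, the classifiers recover planted structure, and the search
localizes planted patches without false alarms on planted-free images.
What they do not show: performance on real CT, where attenuation patterns
are not stationary noise fields, halo rings deform with the bowel wall, and
class overlap is driven by anatomy and contrast phase rather than preset
moments.

## Problem sizes and defaults

Test and reproduction runs use 10–30 windows per class, 64×64 to 110×120
pixel textures, 320×352 phantoms, 20-phantom recall/false-alarm suites, and
10⁶-draw moment checks — sizes at which every generator contract and
stochastic bound in the suites holds with wide margin while the whole suite
runs in well under a minute. All randomness flows through
`numpy.random.default_rng` seeds recorded in the artifacts.

## Known limitations

- Single 2-D slices only; no volumetric features, no Hounsfield
  calibration, no contrast-phase modeling.
- Entropy is the only co-occurrence descriptor (no contrast/homogeneity/
  correlation), and the GLCM is single-offset.
- The box-counting estimate on mean-thresholded grayscale is sensitive to
  the binarization rule; differential box counting is not implemented.
- The search proposes rectangles; it does not segment the bowel wall, and
  morphologic/spatial relations between detections are not modeled.
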