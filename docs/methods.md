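# Methods

## Problem and model

Two fibrous networks of the dermal extracellular matrix — elastin and
collagen — are imaged label-free in separate spectral channels (TPEF
and SHG).  The package quantifies how much the two networks *resemble*
each other in spatial arrangement and morphology, on the premise that
aberrant wound healing (keloid scarring) remodels the two fiber systems
toward each other while normal dermis keeps them organized
independently.  Resemblance is a pixel-wise quantity: it must be high
exactly where elastin and collagen fibers are close, similarly dense,
similarly oriented, similarly ordered, and similarly wavy.

## Feature maps

All maps are defined on fiber-mask pixels only; background is a NaN
sentinel and never enters any statistic or histogram.  The coordinate
convention is row-major with the origin top-left; angles are measured
from the image x-axis, counter-clockwise with y up, axial in [0, 180°).

* **Segmentation** — Otsu threshold on the median-filtered (3×3)
  intensity, objects under `min_object_size` (default 8 px) removed.
  A constant image cannot be thresholded; it returns an empty mask with
  an explicit `status="empty"` flag that downstream stages turn into a
  named error (RM is undefined without both masks).
* **Local coverage (LC)** — fraction of fiber pixels in a disk window
  (radius 16 px default).  Windows are clipped at image edges and
  normalized by the in-image window area, so edge pixels are unbiased.
* **Orientation (Ori)** — eigen-analysis of the Gaussian-smoothed
  structure tensor (σ = 2 px default); the minor eigenvector is the
  fiber axis.  Validated against ribbons at known angles (0°, 45°, 90°,
  135°) to within 3°.
* **Directional variance (DV)** — 1 minus the mean resultant length of
  doubled-angle unit vectors over mask pixels in a disk window (radius
  16 px).  Doubling identifies θ with θ+180° and makes perpendicular
  pairs cancel.  An isolated pixel sees only itself: DV = 0.  DV is
  invariant under a global rotation of all fibers.
* **Waviness (Wav)** — skeletonize the mask, split the skeleton into
  simple chains at junction pixels, and slide a window of fixed arc
  length (32 px default) along each chain: waviness is 1 − chord/arc of
  the window, propagated from the skeleton to all mask pixels through
  the Euclidean feature transform.  Straight fibers give ≈0 (skeleton
  pixelation keeps it below 0.05); a circular arc gives a constant; the
  value grows monotonically with the phantom generator's waviness dial.
* **Thickness** — medial-axis distance transform: at each skeleton
  pixel the width is 2d − 1 pixels (d the distance to background), so a
  one-pixel line reads exactly one pixel wide and an n-pixel ribbon
  reads within one pixel of n; widths propagate to all mask pixels and
  convert to μm.  Thickness is restricted to the elastin channel:
  collagen's entangled texture has no resolvable single-fiber width,
  and passing a collagen mask is a contract error.

Window radii are configuration, not constants; defaults are logged in
every provenance record because no canonical values exist for them.

## The resemblance metric

1. **Pairing.**  Exact Euclidean distance transforms with index maps
   give, for every elastin pixel, its nearest collagen pixel and
   distance (μm), and vice versa.  The relation is asymmetric and both
   directions are preserved; the implementation is verified to match an
   O(N²) brute-force oracle exactly.
2. **Differences.**  At each fiber pixel, |own feature − partner's
   feature|.  Orientation differences wrap to the complementary angle
   above 90° (wrap happens before fusion, so overlap pixels average two
   already-wrapped values; this choice is recorded in the provenance
   log).  Distance acts as a pseudo-feature whose underlying map is
   identically zero, so its difference is the pairing distance itself.
3. **Fusion.**  On elastin-only pixels the elastin-side difference, on
   collagen-only pixels the collagen side, on the overlap the average.
   The fused map's domain is exactly the mask union.
4. **Scores.**  Distance: S = 1/(1 + (x/Duplim)(e−1)), where Duplim is
   recomputed per image as the maximum of the elastin thickness map —
   the score is 1 at contact and 1/e at one maximal fiber width, so
   "near" is measured in units of fiber size, making the ratio
   unit-free (both distance and thickness in μm).  Coverage:
   S = 1/(1 + x(e−1)), the same hyperbola on the [0,1] difference.
   Orientation: S = cos x.  Collective features (DV, Wav):
   S = ½[1 − tanh C(x − ½)] with C = 4, a decreasing sigmoid through
   (½, ½) satisfying S(x) + S(1−x) = 1; C sharpens contrast at
   intermediate differences and is adjustable for other tissue models.
   The raw antisymmetric form −½·tanh C(x−½) is selectable via
   `shifted_sigmoid=False` for auditing only: its (−½, ½) range is
   incompatible with a [0, 1] product metric, which is why the shifted
   form is the default (see "Design choices").
5. **Combination.**  RM = Π Sᵢ^{wᵢ} elementwise, defaults wᵢ = 1
   (plain Hadamard product).  Weights are exponents so that wᵢ = 1
   reproduces the unweighted product exactly and wᵢ = 0 removes a
   feature.

A useful closed-form anchor: feeding the same image as both channels
makes every difference zero, so S_D = S_L = S_O = 1 while the two
collective scores each equal ½(1 + tanh 2) ≈ 0.98201, giving a
spatially constant RM = (½(1+tanh 2))² ≈ 0.96435.  The test suite
checks this ceiling to 1e−9.

### Degenerate inputs and numerical choices

* Empty mask in either channel → error naming the channel.
* Duplim ≤ 0 (empty or single-point elastin skeleton) → error unless a
  `duplim_floor` (μm) is configured.
* All score maps clamp only by construction (the closed forms cannot
  leave [0,1]); declared ranges are asserted at container construction.
* Distances use the exact Euclidean transform, not a chamfer
  approximation; ties between equidistant partners resolve to the
  transform's canonical index, which affects only which of several
  equal-distance partners supplies the feature value.

## Per-sample statistics

Twenty indicators per sample: mean and SD of the ten maps (LC, Ori, DV,
Wav × two channels; elastin thickness; RM), computed over mask pixels
only.  Map-level SDs use the population convention (pixel counts are
thousands; the n−1 correction is negligible but the choice is fixed and
documented).  Replicate-level coefficients of variation use the sample
(n−1) SD: CV = sd/mean × 100%.  Orientation means are arithmetic on
[0, 180°) to match linear orientation histograms; a circular
(doubled-angle) mean is available behind a flag because the arithmetic
mean biases toward 90° when the distribution straddles the 0/180 wrap.
One image is one sample; no multi-field pooling is performed.

## Feature selection and classification

* **Ranking** — XGBoost multiclass model; importance is split
  frequency ("F score") summed over all trees; unused features score 0
  and sort after used ones, ties broken by column order.
  Hyperparameters (learning rate, depth, subsample, min child weight)
  come from Gaussian-process Bayesian optimization (Matérn 5/2 kernel,
  expected-improvement acquisition, 12-evaluation budget with 6 random
  initial draws) of stratified 5-fold CV accuracy, with early stopping
  (10 rounds) on a held-out fold.  `colsample_bytree=0.7` is fixed: a
  tree-level column subsample decorrelates importance among collinear
  features, so near-duplicate informative columns both accumulate
  splits instead of one absorbing all of them.
* **Incremental selection** — top-n subsets for n = 1..20, each scored
  by 5 repeats of stratified 5-fold CV.  The optimal n is the smallest
  n whose mean accuracy is within one pooled SD of the global maximum:
  a reproducible reading of "the accuracy plateau starts here".
* **KNN** — k = 6 default; features z-scored with the scaler fit
  inside each training fold (no leakage).  OCA fits and scores on all
  samples; CVCA is leave-one-out.  ROC scores are neighbor-vote
  fractions, one-vs-rest per class, AUC by the trapezoidal rule.

Everything is seeded; identical table + config + seed reproduces the
ranking, the curve, and the report bit-identically.

## Synthetic phantoms

The generator emulates the study design (three tissue classes, paired
two-channel images) because no public paired elastin/collagen dataset
exists.  Fibers are random-walk polylines: a per-fiber axial base
direction drawn from a von Mises distribution on the doubled circle
(concentration κ; κ = 0 is isotropic), a sinusoidal tangent modulation
of amplitude `waviness_amplitude` radians (wavelength 30 μm), sampled
at 0.5 px steps, clipped at a one-thickness margin around the image.
Ribbons render by thresholding the distance to the path at
thickness/2 with a 1 px linear anti-alias ramp, so the 0.5 level set
sits at the nominal half-width and the ground-truth mask has known
thickness.  Noise is additive Gaussian (SD as a fraction of max
intensity), clipped to [0, 1].

Coupling: in `coupled` mode each collagen path is the matching elastin
path displaced by `coupling_offset` μm along the normal to its chord
(random sign) and rotated about its centroid by N(0, jitter²) degrees.
Offset 0 and jitter 0 give bit-identical channels; increasing either
dial lowers RM monotonically (verified on 3-point grids).  In
`independent` mode the collagen fiber set is drawn afresh.

Default three-class templates differ *only* in coupling strength —
keloid-like: offset 0.2–0.8 μm, jitter ≤ 2°; adjacent-like: offset
3.5–4.5 μm, jitter 10–14°; normal-like: offset 9–11 μm, jitter 35–45°
— with all morphology dials shared.  The gaps are set so the classes
separate by at least three within-class SDs of RM mean, the regime in
which a planted coupling signal should be recoverable end-to-end; the
published study gives no quantitative per-class morphology, so the
templates reproduce orderings (keloid > adjacent > normal in RM mean),
not magnitudes.

What the phantoms do **not** emulate: optical point-spread functions,
shot noise, depth attenuation, collagen's entangled sub-resolution
texture, intensity heterogeneity along fibers, and real biological
covariation between morphology and class.  Passing tests therefore
demonstrate algorithmic correctness and end-to-end signal recovery
under controlled conditions, not clinical performance.

## Problem sizes

Validation runs use 128×128 px phantoms (pixel size 210/256 ≈ 0.82
μm/px, matching a 210 μm field of view on a 256 grid scaled down), a
36-sample cohort (12 per class), 20-permutation nulls, and 5-seed
ranking-stability checks; oracle comparisons use 32×32 masks where the
O(N²) brute force is exact and cheap.  These sizes were chosen so the
whole suite runs in about a minute while keeping every statistical
check comfortably powered.

## Design choices where the design was open

* **Collective-feature score.**  The antisymmetric sigmoid
  ½(e^{−C(x−½)} − e^{C(x−½)})/(e^{−C(x−½)} + e^{C(x−½)}) =
  −½ tanh C(x−½) has range (−½, ½), which cannot produce a product
  metric in [0, 1].  The implemented default adds ½ — the unique
  vertical shift that is decreasing, maps ½ → ½, and lands in (0, 1) —
  and the raw form stays available behind a flag for auditing.
* **Per-feature algorithms.**  The concrete estimators (structure
  tensor for orientation, doubled-angle circular variance for DV,
  chord/arc skeleton waviness, medial-axis thickness, disk-window
  coverage) were chosen as the standard published definitions that
  reproduce each feature's declared range and ordering, and each is
  validated against phantom ground truth rather than against any
  reference map.
* **Orientation fusion order.**  Differences wrap to the complementary
  angle before fusion (wrap-then-fuse); the alternative (fuse raw
  differences, then wrap) differs only on overlap pixels.  The choice
  is recorded in every provenance log.
* **Distance units.**  Pairing distances and thickness are both in μm,
  so the distance score's ratio is dimensionless regardless of pixel
  size.
* **Optimal-n rule.**  Published subset choices by inspection are not
  reproducible; the one-pooled-SD-of-maximum rule is a pure function of
  the curve.

## Known limitations

* Arithmetic orientation means bias toward 90° for distributions
  straddling the axial wrap (the circular option exists but is off by
  default for histogram comparability).
* Waviness depends on skeleton quality; heavily blobbed masks (many
  junctions) shorten chains and deflate waviness near crossings.
* Thickness at fiber crossings reports the width of the merged blob,
  which inflates Duplim on dense phantoms; this is faithful to the
  definition (maximum of the thickness map) but makes the distance
  score more forgiving as density grows.
* The leave-one-out permutation null is slightly pessimistic (the held
  out sample's class is underrepresented in training), so permuted
  accuracies and AUCs center just below chance; chance recovery is
  judged against the permutation distribution's own spread.
* 2-D only; no volumetric fiber tracking.
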