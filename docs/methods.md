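# Methods

`readiff` models how *difficult* a screening mammography case is for a
cohort of readers, using only global image texture.  This note documents
the statistical model, the synthetic world the package ships in place of
clinical data, the numerical choices, and what the tests do and do not
establish.

## Problem and labels

A panel of readers rates every case on the 5-point RANZCR suspicion scale
(1 normal, 2 benign, 3 indeterminate, 4 suspicious, 5 definitely
malignant) and may annotate suspicious locations.  A rating of 3 or more
is a positive call.  Three error bases are scored per case:

* **FP** — a positive call on a cancer-free case;
* **FN** — a negative call on a cancer case ("case-based" difficulty);
* **location** — failure to localize a cancer within a fixed radius of the
  true lesion ("lesion-based" difficulty).  The radius default is 250 px
  at clinical resolution; the boundary is *inclusive* (distance exactly
  equal to the radius counts as correct), a choice this package fixes and
  documents because convention varies.  Only each reader's highest-rated
  annotation per case is scored.  By default every reader enters the
  location denominator — a reader who misses the case entirely cannot have
  localized it — with a `positives`-only denominator available by flag.

The per-case **error proportion** (fraction of readers committing the
error) is ranked and split into three near-equal tertiles: *easy*,
*median*, *difficult*.  Ties are broken by case id so labels are
reproducible under input permutation; when n is not divisible by 3 the
easy, then the difficult group absorb the remainder.  The median tertile
is excluded from modelling, which accentuates the contrast the classifier
must learn.

## Image processing

Views are canonicalized chest-wall-left (right-side views mirrored).
Segmentation is Otsu thresholding on a Gaussian-smoothed copy
(sigma 3 px — smoothing makes the breast/background split dominate Otsu's
histogram rather than the breast's own texture), largest 4-connected
component, morphological opening (disc radius 5, configurable), hole
filling.  On MLO views the pectoral muscle is removed: Canny edges
(sigma 2) restricted to the chest-wall upper quadrant of the mask, a
straight-line Hough transform, and the highest-vote line inclined 10-80
degrees from vertical; mask pixels on the chest-wall side of the accepted
line are dropped.  If no line clears the vote threshold the mask is
returned unchanged — a deliberate no-detection path.  Line localization is
reliable at the generator's native 256 px scale (on 60 synthetic MLO views:
>= 95% of the wedge removed, <= 2% of breast lost, no missed detections);
at 128 px the line is occasionally a few degrees steep.  The reduced-scale
end-to-end runs use the central square ROI, which an over-cut pectoral
cannot reach.

Three ROIs are delineated per view:

* **square** — the largest axis-aligned square inside the mask, found by
  binary search on the side length over an integral image; ties go to the
  smallest top-left row, then column.
* **retroareolar** — a square of side 0.25 x breast depth (horizontal mask
  extent) centred on the nipple point, defined as the mask contour point
  farthest from the chest wall.  The 0.25 factor and the nipple heuristic
  are modelling choices (configurable), not field standards.
* **whole** — the mask bounding-box crop.

Out-of-mask pixels are *excluded* from every statistic rather than
zero-filled, so background never contaminates histograms or texture
matrices; texture matrices treat them as invalid neighbours.  Each ROI is
carried in both a raw and a z-scored track (mean 0, SD 1 over in-mask
pixels, population SD); both tracks are analysed because normalization may
help or hurt depending on whether readers saw vendor-processed images.

## The 203-feature bank

Twelve families, counts frozen in a machine-readable registry
(`readiff.radiomics.registry_json()`); names and order are stable API:

| family | n | definition |
|---|---|---|
| histogram | 28 | first-order statistics incl. 8 percentiles, IQR, trimmed mean, 64-bin entropy/uniformity/mode/peak |
| GLCM | 88 | 22 statistics x 4 offsets (0/45/90/135 deg, distance 1, symmetric; offsets kept separate) |
| GLRLM | 7 | SRE, LRE, GLN, RLN, RP, LGRE, HGRE averaged over 4 directions |
| GLSM | 6 | moments + entropy of the Sobel gradient magnitude |
| GLDS | 15 | mean/contrast/ASM/entropy/IDM of direction-pooled |diff| histograms at d = 1, 2, 4 |
| NGTDM | 15 | Amadasun coarseness/contrast/busyness/complexity/strength at windows 3, 5, 7 |
| SFM | 8 | coarseness/contrast/periodicity/roughness at max spacing 4 and 8 |
| Laws | 18 | mean + SD of 9 direction-averaged 5x5 texture-energy maps |
| fractal | 2 | box-counting dimension + gliding-box lacunarity of the above-mean set |
| Gabor | 6 | mean |response| at 2 frequencies x 3 orientations |
| RFS | 8 | mean energy of the 8 MR8 maximum-response maps (25 px support) |
| Fourier | 2 | radial log-log power slope + high-frequency power fraction |

Choices worth noting:

* Matrix families run on an equal-width 32-level quantization of the
  in-mask intensity range (configurable; equal-width makes the levels
  affine-invariant, so z-scored tracks of affinely related images quantize
  identically).
* The GLCM statistic list keeps the thirteen classic Haralick measures
  plus nine widely used extras; "variance" is the moment about the
  marginal mean while "sum of squares" is the raw second moment — the two
  would otherwise coincide.  Value-weighted statistics index grey levels
  1-based.  Degenerate denominators (constant matrices) return 0 so every
  feature is finite on any non-constant input.
* The fractal dimension is binary box counting of the above-mean pixel
  set: a filled uniform region scores ~2.0 and sparse dots score < 2.
  The differential (surface) variant was deliberately not used; the binary
  variant has the stated extreme-case behaviour.
* Filter families (GLSM, Laws, Gabor, MR8, Fourier) crop to the valid
  bounding box, fill interior invalid pixels with the in-mask mean, and
  restrict output statistics to valid pixels; all families are therefore
  exactly invariant to padding the ROI with invalid pixels.
* The MR8 bank uses sigma pairs (1,3), (2,6), (4,12) on a 25x25 support
  (truncation of the largest filter documented here); ROIs smaller than
  the support raise an error, which bounds the minimum usable ROI at
  25 px.

Every matrix-based family is tested against naive double-loop oracle
implementations on random masked 8x8 patches; the co-occurrence counts are
additionally cross-checked against scikit-image on fully valid patches.

## Classifier

Per view, a random forest classifies easy vs difficult.  For cancer-free
cases four view models are trained (LCC, RCC, LMLO, RMLO — a false
positive can arise anywhere); for cancer cases only the two lesion-side
views enter.  Case-level prediction is **maximum-probability fusion** over
views: a case should surface as difficult if even one view is difficult.

Validation is nested: leave-one-case-out outside (all views of a case
travel together), label-stratified 3-fold x 3-repeat cross-validation
inside.  The grid — trees {50, 100, 500, 1000}, max sample fraction
{0.10, 0.50, 1.00}, depth {1, 5, 10}, selected features
{8, 16, 32, 64, 203} — is searched exhaustively, scored by the mean
view-level inner AUC over the nine inner splits (tuning on the view level,
not post-fusion, is a package choice; a fused-criterion variant would be a
one-line change in `nested_cv`).  Feature selection is embedded: a forest
on all features ranks them by mean-decrease-impurity, the top k are kept
(ties broken by registry order), and when k equals the full bank the
ranking forest *is* the fitted model.  The winning cell is refit on the
full outer-training set.  The pooled outer predictions form one ROC curve
— the only way leave-one-out yields a single AUC.  All randomness derives
from one seed through named `numpy.random.SeedSequence` substreams (inner
fold plan, per-view forests), so runs are bit-reproducible.

The feature-count grid values are package defaults (the number of selected
features is tuned, but no canonical value set exists); whether the four
cancer-free view models should share hyperparameters was an open choice —
they are tuned independently here.

## ROC statistics

AUC is the Mann-Whitney U-statistic with tied pairs half-weighted.
Operating metrics default to threshold 0.5 (a Youden-point helper is
provided; no principled threshold exists for pooled LOO probabilities).
Confidence intervals are percentile (2.5/97.5) from a 2000-replicate
stratified bootstrap — positives and negatives resampled independently, as
in pROC with stratification — and the reported interval is clipped to
bracket the point estimate.  Two comparison procedures:

* **Unpaired bootstrap z-test** for independent cohorts (each cohort's
  tertile exclusions yield different case sets): both cohorts resampled
  stratified, z = dAUC / SD(dAUC*), two-tailed normal p.
* **DeLong's test** for paired scores on identical cases, via structural
  components; identical score vectors return p = 1 exactly.

Calibration is tested, not assumed: DeLong's null rejection rate over 500
paired-noise simulations must land in [0.03, 0.07] at alpha 0.05, and
bootstrap CI coverage over 200 binormal simulations in [0.90, 1.00].

## The synthetic world

No public mammography dataset carries reader-error panels, so the package
generates one.  Each case is four views of a clustered lumpy background —
the standard texture model in medical image perception research — inside a
half-disc silhouette (radius 0.46 x image size) on a dark background: 60
to 100 Gaussian blobs, amplitudes U(0.5, 1.0) over a tissue floor of 1.0,
pixel noise SD 0.02, written as 16-bit PNG.  MLO views add a bright
triangular pectoral wedge (default 25 degrees from vertical, +1.5
intensity).  Cancer cases place one Gaussian lesion (sigma 5 px, contrast
0.8) at a recorded location in the CC and MLO views of one side.

All blobs in a case share one width sigma_c ~ U(2, 8) px; the **latent
difficulty** d_c is sigma_c standardized over the cohort, so coarse
textures are difficult.  Making d_c a generator parameter — not an
extracted feature — means recovering it downstream genuinely exercises
segmentation, the feature bank and the classifier.  Reader r errs on case
c with probability

    sigmoid(alpha + beta * d_c + b_r),    b_r ~ Normal(0, reader_bias_sd)

Defaults: alpha = -0.85 (a ~30% baseline error proportion, the mid-range
of plausible screening-error enrichment in a test set), beta = 2.0,
reader_bias_sd = 0.5.  No empirical per-reader performance distribution
was available to calibrate the bias SD; it is an arbitrary but documented
default.  On cancer cases an error is, with probability 0.3, a
localization error — rating 3-5 with an annotation drawn uniformly on the
annulus (radius, 2 x radius] around the lesion (rejection-sampled onto the
breast, and re-drawn if pixel rounding would land back inside the correct
radius) — otherwise a false negative (rating 1-2, no annotation).  The
synthetic correct-localization radius defaults to image_size / 8 because
the clinical 250 px rule does not transfer to small rasters.

What the generator does **not** emulate: anatomy (ducts, vasculature,
skin line), vendor post-processing, reader fatigue or reading order,
inter-lesion heterogeneity, and any correlation between lesion
conspicuity and background other than through d_c.  A green end-to-end
test therefore establishes that the pipeline recovers a known
texture-to-error coupling through the full image path — not that it
predicts clinical reader behaviour.

## Runtime scaling of stated checks

Heavy checks run scaled down, never gated off:

* The end-to-end recovery check (60 cases, 20 readers, beta = 5, FP basis,
  reduced grid: 100 trees, depth 5, full sample, k in {16, 203}) runs at
  image_size 128 with the square ROI only (~8 min on one CPU).  With
  beta = 5 the pooled LOO AUC must reach 0.75; with beta = 0 the 95%
  bootstrap CI must cover 0.5.
* The null-permutation check of `nested_cv` uses 25 permutations, and the
  DeLong-vs-paired-bootstrap agreement check 4 trials of 4000 replicates.

## Known limitations

* Pectoral-line localization degrades below ~256 px image size; the
  retroareolar ROI needs >= 25 px of side (breast depth x 0.25) to fit the
  MR8 filter support.
* `nested_cv` is O(outer x channels x grid x 9) forest fits; the full
  paper-scale grid (180 cells) at 60 cases is hours on one CPU — use the
  reduced grid for exploration.
* The exact statistic registries inside each texture family are package
  choices; only the family counts are externally fixed.  Feature *values*
  are therefore not comparable to other radiomics toolkits, though the
  family semantics are.
* DICOM input is not supported (no DICOM reader in the dependency set);
  views are read from PNG/TIFF.
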