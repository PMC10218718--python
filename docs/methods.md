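# Methods

This note documents the models and procedures implemented in `tsr-slide`,
the parameter choices that matter, what the synthetic data does and does not
emulate, and the package's known limitations.

## The TSR estimation pipeline

A whole-slide image is scored in four stages: tissue masking, tiling,
per-patch classification, and the ratio statistic.

**Tissue mask.** Background and adipose tissue both appear near-white under
H&E, so one binary mask removes both. The mask channel defaults to HSV
saturation (stained tissue is strongly saturated, background and fat are
not), with grayscale available by flag; the threshold is Otsu's optimum,
computed from the 256-bin histogram as the split maximizing the
between-class variance ω₀ω₁(μ₀−μ₁)². Ties take the lowest maximizing bin,
which makes the threshold deterministic. No morphological cleanup is applied
by default (`min_object_px = 0`); real scanner output usually wants a small
positive value.

**Tiling.** Windows are 224 × 224 px, half-open `[x, x+224) × [y, y+224)`,
0-based, enumerated row-major; partial windows at the right/bottom edges are
dropped. Training tiling strides by 160 px (64 px overlap) over an annotated
slide and keeps a window iff at least 75% of its pixels carry an annotation
of any tissue class; the patch label is the majority annotated class, with
ties resolved in the fixed order tumor > stroma > other. Inference tiling
strides by the window size (no overlap) and keeps windows with at least 75%
mask coverage. Both 75% thresholds are inclusive: a window at exactly 75%
is kept, since only windows *below* the bound are discarded.

**Stain normalization (Macenko).** Under Beer–Lambert, transmitted
intensity relates to stain concentrations by `OD = −log10(I/I₀) = S·c` with
`S` the 3 × 2 matrix of unit-norm H and E absorption vectors. Per patch:

1. pixels with channel-mean OD below β = 0.15 are discarded (a "mean"
   criterion; the classic "every channel above β" variant is a config
   option — the mean form does not silently discard strongly eosinophilic
   pixels, whose red OD is naturally tiny);
2. the two leading eigenvectors of the OD covariance span the stain plane;
3. projected polar angles are reduced to their α and 100−α percentiles
   (α = 1), giving the extreme directions of the two-stain mixture cone —
   the stain vectors; vectors are sign-corrected, clipped to the
   non-negative octant and unit-normalized, and the more blue-heavy column
   is labeled hematoxylin;
4. concentrations are solved by least squares with negatives clipped to
   zero (an exact non-negative solve is a flag; it matters only for nearly
   collinear stains), and the per-stain 99th percentile becomes the robust
   maximum concentration.

Normalization rescales a patch's concentrations by the ratio of reference
to source maxima and re-renders them through the reference matrix. Fewer
than 50 usable pixels raises an "insufficient tissue" error; in bulk
scoring the configured fallback passes the patch through unchanged with a
warning. I₀ = 255, OD in log base 10. One global reference stain model
(the standard H ≈ (0.65, 0.70, 0.29), E ≈ (0.07, 0.99, 0.11) vectors,
unit-normalized, maxima (1, 1)) is used everywhere by default;
per-dataset references can be supplied.

**Classifier.** Three classes (tumor, stroma, other) through a softmax of
dimension 3; the class order is fixed and recorded with the model. The
default backbone is a small numpy CNN: patches are block-averaged to
32 × 32 × 3 and passed through two 3 × 3 conv + ReLU + 2 × 2 max-pool
blocks (8 and 16 channels) and a linear head (~4.5k parameters),
trained with cross-entropy under Adam (default lr 0.005, batch 32) or SGD.
Being pure single-threaded numpy, training is bit-reproducible for a fixed
seed. The backbone is pluggable: anything exposing the same
`fit`/`predict_proba` surface (e.g. published large architectures, where
their framework is available) can stand in; nothing else in the pipeline
depends on the default network.

**Transfer-learning setups.** The three pre-training sequences differ only
in initialization and whether a domain-specific source dataset precedes
fine-tuning:

* SETUP-1: shared pretrained initialization → pre-train on the domain set →
  fine-tune on the target set;
* SETUP-2: shared pretrained initialization → fine-tune directly;
* SETUP-3: random initialization → pre-train on the domain set → fine-tune.

For the numpy backbone the "shared pretrained initialization" is one fixed,
documented parameter draw used identically by every run — what the setups
compare is the pre-training *sequence*, and that structure is preserved at
desk scale. Every stage executed (initializer, pre-training, CV, early
stopping, fine-tuning) is recorded in the model's provenance.

**Model selection.** Hyperparameters come from 5-fold cross-validation on
the training patches: shuffled folds of near-equal size, each fold held out
once, candidates scored by mean held-out-fold accuracy, ties keeping the
earlier grid entry. The epoch budget comes from early stopping: one third
of the training patches are held out, training stops when validation
accuracy has not improved for `patience` epochs (default 5), and the
earliest epoch achieving the best validation accuracy wins. The final model
is then retrained on the full training set for exactly that many epochs,
restarting from the pre-fine-tuning parameters.

**TSR.** Per slide, `TSR = n_stroma / (n_tumor + n_stroma)` over the
classified inference patches. *Other* patches are excluded from numerator
and denominator, so the statistic is exactly invariant to them; swapping
the two counts maps TSR to 1 − TSR. A slide with no tumor or stroma patches
raises an explicit error rather than reporting 0. TSR is stored as a
fraction and rendered as percent; dichotomization is strict:
TSR > cutoff (default 50%) is stroma-high, at or below is stroma-low.
A median-of-cohort cutoff is supported as a variant.

**Evaluation.** Classifier quality: 3 × 3 confusion matrix (rows true),
accuracy, per-class precision/recall/F1, with 0/0 divisions reported as 0
and flagged, never NaN. TSR quality against visual scores on the
{10, …, 90} grid: per-category mean, median, standard deviation and SEE,
overall Pearson r, overall SEE, and Cohen's κ of the dichotomized calls.
SEE — the standard error of the estimate — is defined as the RMS deviation
of predicted TSR from the assigned category value (denominator n); this is
the definition under which a category's SEE² decomposes as std² + bias².
The standard deviation uses n−1 by default (n by flag). κ uses the
marginal-product expected agreement; two constant, identical raters get
κ = 1 by convention.

## The synthetic forward model

Slides are rendered by the exact Beer–Lambert model the normalizer assumes:
per-pixel H/E concentration fields, `I = I₀·10^(−S·c)`, optional Gaussian
sensor noise (σ = 1.5 intensity units) and uint8 quantization. An
unquantized mode renders the noiseless float forward model, which
`rgb_to_od` inverts to machine precision. Layouts (uniform canvases,
vertical bands, quantile-split Gaussian-field blobs with exact per-class
area fractions) resolve to a pixel-exact label map; ground truth carries
the label map, per-class areas, the generating stain model, per-class mean
concentrations, and the expected patch-count TSR computed by a direct
brute-force scan of the label map that is independent of the production
tiler.

Class appearance follows the tissue chemistry: tumor is
hematoxylin-dominant with dense nuclear speckle; stroma is eosin-dominant
with a gentle fibrous modulation and sparse fibroblast nuclei; adipose and
background are near-white (all channels ≥ 0.85·I₀). Two renderings with the
same seed and different stain models share identical concentration maps.

Three generator choices are load-bearing and deliberate:

* **Pure-stain speckles in every tissue class.** Real H&E tissue is
  counterstained: nuclei are nearly pure hematoxylin, collagen and dense
  cytoplasm nearly pure eosin. Each class therefore renders a few percent of
  its area as near-pure speckles of both stains. This anchors the extreme
  angle percentiles Macenko relies on (without pure-ish pixels the
  percentile directions underestimate the stain cone) and gives every class
  a comparable 99th-percentile concentration, so per-patch normalization
  applies a mild, uniform intensity rescale instead of amplifying whichever
  stain a homogeneous patch lacks — a known failure mode of per-patch
  Macenko on single-stain tissue.
* **A two-phase grab-bag class.** *Other* collects debris, mucus, normal
  epithelium and smooth muscle; it is rendered as a coarse mottle of
  basophilic and eosinophilic phases rather than one intermediate color.
  Windows mixing tumor and stroma then resemble *other* and drop out of the
  TSR counts roughly symmetrically instead of systematically inflating one
  side.
* **Tissue fields large relative to the window.** Cohort slides
  (`make_tsr_cohort`: 1568², tissue 88% of the canvas, stroma share swept
  0.22–0.88, blob scale 1000 px) keep contiguous tumor/stroma fields much
  larger than the 224-px window, as in resection specimens at 0.5 MPP;
  window-level class mixing is confined to region boundaries.

For classifier development, `sparse_annotation` erodes each class region
(default margin 56 px) before annotating, emulating an expert who annotates
homogeneous regions and avoids boundaries; windows straddling a class
boundary then fail the 75%-annotated filter exactly as they would on an
expert-annotated slide.

Ground-truth TSR is defined at the patch-count level (matching the ratio
statistic); the pixel-area ratio is reported alongside, and the two differ
at region boundaries.

What the generator does **not** emulate: nucleus-level morphology,
scanner artifacts (blur, pen marks, tissue folds), stain fading, the visual
similarity of smooth muscle and fibrotic stroma that drives real
stroma/other confusion, and pathologist spot-selection in visual TSR
scoring. Passing tests therefore demonstrate the correctness of the
pipeline's mechanics and its behavior under a controlled forward model —
not clinical-grade accuracy on real slides.

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds; workflows derive
  per-stage seeds by hashing the stage name into the global seed (stable,
  collision-free across stages, below 2³¹).
* Otsu: degenerate (single-bin) histograms raise; a blank slide yields an
  all-false mask with a warning instead.
* Stain estimation: a rank-deficient OD cloud (single pure stain, blank
  patch) raises "insufficient tissue"; callers choose between erroring and
  pass-through.
* argmax ties (class prediction, majority labels, CV candidates, early-stop
  epochs) always resolve to the first/lowest index, so every selection is
  deterministic.
* Patch downsampling is exact block averaging when the patch size is a
  multiple of the network input (224 → 32), bilinear otherwise.

## Desk-scale problem sizes

The validation suite and the reproduction script run the full protocol at
sizes a laptop CPU handles in minutes: 600 training patches per class,
12 training epochs maximum, 30-slide cohorts of 1568² px slides (49
windows each), 50 random stain models for the recovery study. These sizes
are the package's test conditions, chosen to make every stage measurable
while keeping runs interactive; the pipeline itself has no built-in limits
and scales with the input.

## Known limitations

* The default backbone is intentionally small; reproducing published
  accuracies of large architectures on clinical cohorts requires plugging
  in those architectures and data.
* Per-patch stain estimation remains less stable on homogeneous real tissue
  than on the synthetic forward model; a slide-level source estimate can be
  passed to `normalize_patch` where that matters.
* Mixed tumor/stroma windows are genuinely ambiguous under a 3-class patch
  model; the TSR error this induces shrinks with window size relative to
  region size but does not vanish.
* Visual TSR is scored by pathologists at a selected spot, while this
  pipeline scores the whole tissue area; the two protocols measure related
  but not identical quantities ("hotspot" scoring is out of scope).
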