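# Methods

This note documents the models, defaults and design choices behind the
`bodymaps` pipeline, in the order the data flows.

## Canvas and template

All maps live on a single-panel raster grid (0-based, origin top-left,
stored `(row, col)`; `col` is x in event files). Activation and
deactivation panels share one template; events carry a panel tag rather
than doubling the canvas. The default template is a procedural,
left-right symmetric humanoid built from stacked ellipses and bands
(head, neck, torso split into chest/abdomen, shoulder-attached arms,
hands, legs), with small cheek disks as a named sub-region. It is a
geometric stand-in, not anatomical artwork: its purpose is to provide a
deterministic, connected in-body mask with named regions at any canvas
size ≥ 40×80. The desk-scale default is 60×120 (2,336 in-body pixels);
real silhouette artwork can be loaded from a grayscale PNG with
`load_template`, in which case the in-body pixel count is whatever the
artwork defines. Regions may overlap (cheeks ⊂ head) and every region is
clipped to the mask.

## Painting model (synthetic cohorts)

A subject's latent sensation field for a stimulus is the planted signed
topography plus i.i.d. Gaussian noise per in-body pixel
(`subject_noise_sd`, default 0.5 in latent units). Pixels with field
above `paint_threshold` (default 0.5) become activation click centers,
below the negative threshold deactivation click centers; centers are
subsampled uniformly without replacement to at most 400 per panel to
emulate finite mouse strokes. Ordinary painters click only inside the
silhouette — the web instrument displays the outline, and out-of-body
painting is precisely what marks an anomalous responder. Anomalous
subjects (per-subject probability `anomaly_rate`) ignore the truth and
draw a fixed plus-sign glyph whose horizontal bar spans the full canvas,
spilling outside the body. Each (subject, stimulus) map is attempted
with probability `completion_prob` (default 0.95).

The default 20-stimulus topography pack (14 emotions + 6 phenomena)
encodes the qualitative layout reported for this task family: sadness,
depression and the neutral state dominated by limb deactivations;
disgust positive along the digestive tract; shame activating the
cheeks; the global phenomena (climate change, COVID-19, war) activating
head, chest and abdomen, with COVID-19 adding leg deactivations and
climate change hand activations. Amplitudes (0.3–1.3 latent units) were
chosen once so that strong components sit near signal-to-noise 2 under
the default noise, weak ones (neutral state, nature) below the paint
threshold so they are painted only when noise pushes them over —
mimicking the near-empty neutral map seen in real cohorts.

What the generator does **not** emulate: spatial autocorrelation in the
noise field (noise is white before thresholding; smoothing reintroduces
spatial structure downstream), stroke dynamics and response times,
demographic structure, inter-stimulus correlations within a subject
(each map draws fresh noise), and the idiosyncratic per-subject response
styles of real painters. Passing tests therefore demonstrate that the
*pipeline* is correct and well calibrated, not that real cohorts will
reach the same effect sizes; real-data accuracies are far below the
synthetic ones because real between-subject variability is structured
and much larger.

## Subject-map reconstruction

Rasterization paints the discrete disk `{dr² + dc² ≤ r²}` around each
click center, saturating at 1 — painting is set-valued, the tool records
coloured regions, not stroke counts. Smoothing convolves with a unit-sum
Gaussian kernel truncated at 3σ with zero padding, so mass is conserved
for support ≥ 3σ from the border; σ = 0 is the identity. Defaults
`brush_radius = 6`, `sigma = 5` px are scaled to the 60×120 canvas (the
web instrument's own kernel parameters are not public; both are
configuration). The signed map is
`smooth(raster(activation)) − smooth(raster(deactivation))`, and the
body mask is applied **after** smoothing so paint bleeding across the
outline is zeroed rather than reflected in. The merge is exactly
additive: `bsm(A, ∅) + bsm(∅, D) = bsm(A, D)`.

## Quality control

A map counts as completed iff at least one event rasterizes to an
in-body pixel. Completion screening excludes subjects whose completed
count is strictly below `mean − k·SD` (sample SD, ddof = 1; default
k = 2.5). At study scale (mean 18.79, SD 2.06) this cutoff is 13.64
maps, i.e. at least 14 completed maps to stay. The screen is computed on
the full cohort before anomaly exclusion; callers who prefer the other
ordering can re-run it on a filtered cohort.

Anomaly detection replaces manual visual inspection with three advisory
heuristics: fraction of clicks outside the silhouette (> 0.25),
painted-area z-score across subjects (|z| > 3.5; unattainable below
n = 13 by the z-score bound (n−1)/√n, so small cohorts rely on the other
two detectors), and a straight-stroke detector (> 55% of a map's clicks
inside one 3-pixel row or column band, for maps with ≥ 30 clicks, in
more than a quarter of the subject's maps). Flags carry human-readable
reasons and never exclude by themselves.

## Group statistics

Per stimulus, subjects missing that map are dropped listwise (n varies
per map). At each in-body pixel, `t = m̄/(s/√n)` with two-sided p from
Student's t at df = n−1. Zero-variance pixels follow a fixed convention:
all-zero samples give t = 0, p = 1 (an untouched pixel is evidence of
nothing); constant nonzero samples give p = 0 with t = ±inf as a
documented sentinel. FDR control is Benjamini–Hochberg step-up over the
m in-mask p-values of each map separately (critical p = largest
`p₍k₎ ≤ kα/m`, default α = 0.05); a `pooled_fdr` mode corrects across
all 20 maps at once, yielding one shared critical p and hence a single
display threshold on |t| for every panel — useful when a figure quotes
one global t cutoff. `min_sig_abs_t` records the smallest |t| among
significant pixels (NaN when nothing survives).

## Similarity

Similarity is Spearman rank correlation between in-mask vectors, with
average ranks for ties; the matrix ranks each map once and takes Pearson
on the rank vectors, which is algebraically identical to pairwise
Spearman. It is computed on **unthresholded** t-maps — thresholding
would zero-inflate the ranks — with a thresholded mode available for
comparison. A constant vector makes the correlation undefined; it is
reported as NaN with a warning, never silently 0, because a nearly
empty map (the neutral state) should be visible as undefined rather
than "dissimilar". Cross-study comparison matches labels
case-insensitively and resamples reference grids to the template by
nearest neighbor; correlating t-maps rather than mean maps is a
convention of this package (both are monotone-related for homogeneous
n, so Spearman is largely insensitive to the choice).

## Classification

Features are the in-mask pixel vectors of completed subject maps. The
default estimator reduces to 30 principal components and fits a linear
discriminant classifier, with stratified five-fold cross-validation
repeated (default 100) times under reshuffled, seeded fold assignments.
The PCA is fit **inside each training fold** by default — no test-set
leakage — with a `global_pca` compatibility flag for replicating
analyses that reduce dimensionality once on all data. Samples from one
subject may appear on both sides of a split by default (stratification
is by stimulus only); `subject_blocked=True` switches to stratified
group CV keeping each subject within one fold. Features are not
z-scored by default (`scale=True` enables it): pixel values share units,
and PCA on the raw covariance weights pixels by actual variance.
Dispersion across iteration accuracies is reported as both SD and SEM,
since either convention appears in the literature. The confusion matrix
aggregates all test predictions over all iterations and is
row-normalized to percentages per true class.

## Validation studies (`bodymaps.experiments`)

* **Parameter recovery** — 100 subjects, 60×120 template, one flat
  +2.0-amplitude region per stimulus (head, chest, abdomen, arms,
  hands, legs), noise SD 1.0 (signal-to-noise 2), paint threshold at
  half amplitude, brush radius 2 and σ = 1 so the planted shapes stay
  resolved at this canvas scale. The recovery target is the noiseless
  painted set — the region dilated by the brush disk, clipped to the
  mask — because the disk brush is part of the forward measurement,
  whereas the sub-threshold smoothing fringe is statistically
  unrecoverable (background painting noise contributes variance at
  every pixel, so pixels whose expected signal is a kernel tail stay
  below any calibrated significance cut). Score: Jaccard overlap of
  FDR-significant activation pixels with that target, typically
  0.92–0.99 per region.
* **FDR calibration** — a 16-subject stack from the painting model is
  made null by flipping each subject's sign with probability 1/2
  (symmetrizing every pixel about zero); over 200 replicates the mean
  false discovery proportion V/max(R,1) — every rejection being false —
  must stay at or below α within binomial Monte-Carlo error.
* **Classification sanity** — the default 20-stimulus cohort at 30
  subjects, 20 CV iterations: accuracy must be at least 3× chance, and
  a label-permuted control must sit within 3 SD of the 5% chance level.

These problem sizes are the package's desk-scale defaults; all scale up
through the same functions.

## Reproducibility

Every stochastic stage takes a seed; the pipeline fans a single
configuration seed out per stage via SHA-256-derived sub-seeds (< 2³¹).
A full `run_all` writes a manifest with the config hash and SHA-256 of
every text artifact; re-running with the same config and seed yields a
byte-identical manifest.

## Known limitations

* The procedural silhouette is not the released artwork; absolute pixel
  counts (and thus any count-dependent quantity) differ from studies
  using the original template, which can be loaded from PNG instead.
* Anomaly heuristics target the simulator's glyph-style anomalies;
  real free-form scribbles may need tuned thresholds or manual review.
* The similarity of t-maps ignores uncertainty in the t-values; no
  significance test is attached to similarity coefficients.
* White-noise painting is a deliberately minimal subject model; effect
  sizes measured on it are upper bounds relative to real cohorts.
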