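# Methods

`milgrade` implements a weakly-supervised pipeline for binary grading of
breast-cancer whole-slide images (WSI): multiple-instance-learning (MIL)
training with multi-task heads, slide-level prediction by top-k majority
vote, tile-probability heatmaps, inter-rater agreement metrics, and
grade-group survival analysis. Because real graded WSI cohorts are
essentially never public, the package also ships a synthetic slide
generator with the statistical structure MIL assumes, so the entire
pipeline is buildable and testable without any data download.

## The MIL model

A WSI is treated as a *bag* of 224×224 tissue tiles at 10× working
magnification carrying a single binary label: high grade (Nottingham
grade 3) versus low/intermediate (grades 1–2). The standard-instance MIL
assumption applies: a bag is positive iff it contains at least one
positive instance.

Training alternates two steps per iteration:

1. **Inference** — up to 512 randomly sampled tissue tiles per slide are
   scored by the current network; the 5 tiles with the highest
   probability of being high grade are selected per slide. Selection
   always uses the tumor-grade head, even when auxiliary heads are
   present.
2. **Training** — the selected tiles, each inheriting its slide's full
   label set, are used for one SGD pass in shuffled mini-batches
   (default batch 256, learning rate 0.007, momentum 0.9, weight decay
   0.01), with random augmentation per tile.

The loss is the unweighted sum of per-task binary cross-entropies
(probabilities clamped at 1e-7); tasks with missing labels are masked
out per sample. Multi-tasking uses hard parameter sharing: all layers
are shared except one dense head per task (tumor grade; optionally
nuclear/tubular/mitotic component labels and HR/HER2 status).

After every iteration the model is evaluated on a held-out validation
split by Cohen's kappa between predicted and reference grade, and the
best-scoring parameters are snapshotted; `train_mil` returns the final
model, the best snapshot and the full per-iteration metric log. At
prediction time a slide's label is the majority vote of its top-5 tiles,
each thresholded at 0.5 (a probability-mean aggregation is available as
an option). `top_k` is forced odd, and when a bag holds fewer tiles the
vote truncates to the largest odd count, so the majority is never tied.

### Interpretation of "iteration" and resampling

One iteration = one full inference pass over all training slides
followed by one training pass over all selected tiles. The 512-tile
sample is redrawn fresh every iteration. Validation kappa is computed
every iteration.

### Backbone

The backbone is pluggable behind a registry. The shipped default,
`smallcnn`, is a three-conv-layer CNN (3×3 convolutions with 8/16/32
channels, ReLU, 2×2 max-pooling, global average pooling, one linear head
per task) implemented directly in numpy with im2col convolutions and
hand-written backprop, trained by SGD with momentum and weight decay. It
trains in minutes on one CPU, which keeps the full loop testable at desk
scale. Tiles are block-averaged from 224 px to the backbone's 32 px
input and scaled to [0, 1]; internally the backbone applies a fixed
standardization ((x − 0.76)/0.2 — typical bright, low-contrast H&E tile
statistics), analogous to the fixed ImageNet normalization of pretrained
backbones. Without centering, a from-scratch network's early gradients
are tiny and the short training budgets used here go nowhere.

Two numerical choices matter for the MIL loop specifically:

- **Zero-initialized heads.** With randomly initialized heads the
  untrained scorer imposes an arbitrary systematic ranking on tiles. If
  that ranking happens to place discriminative tiles last, the top-k
  selection never sees them, the training signal never appears, and the
  loop locks itself out (an anti-selection basin). Zero heads make every
  initial score exactly 0.5; the first selection falls back to the
  deterministic spatial tie-break and carries exactly prevalence-level
  signal.
- **Learning rate by backbone.** The default 0.007 follows the
  finetuning regime of a pretrained production backbone. Training the
  tiny backbone from scratch needs a larger step; the test and example
  configurations use 0.1 for `smallcnn`. With ~5 mini-batches per
  iteration and 30 iterations (~150 updates), 0.007 cannot move a
  freshly initialized network far enough for the selection feedback to
  engage.

Ties in tile ranking are broken by (row, col) lexicographic order for
reproducibility. All randomness (initialization, tile sampling,
augmentation, shuffling, validation) flows from the config seed through
named sub-streams, so a rerun on the same platform reproduces the metric
log exactly.

### Augmentation

Each training tile receives a random 90° rotation, independent
horizontal/vertical flips, and photometric jitter: brightness, contrast
and saturation factors uniform in [1 − m, 1 + m] and a hue shift uniform
in [−m, m] (fraction of the hue circle), with maxima 0.35 / 0.5 / 0.1 /
0.1. No stain normalization is applied; augmentation is the only defense
against staining variability, for the synthetic data and for real slides
alike.

## Tiling

Slides are cut into non-overlapping 224 px tiles in row-major order;
partial edge tiles are dropped (the network input is fixed). A tile is
background iff strictly more than 50% of its pixels are "white", where a
pixel is white when its **minimum** channel is ≥ 240 — the min channel
rather than luminance so that pale eosin regions, which are bright but
pink, survive. Both cutoffs are configurable. `resolve_working_level`
picks the pyramid level closest to the 10× working magnification (log
ratio), accepts it if within 1.5×, and otherwise reads the nearest finer
level and downsamples by the exact remaining factor; single-level images
(such as the synthetic slides) resolve to level 0 with the residual
factor applied by resampling.

## Nottingham grading arithmetic

Component scores (nuclear pleomorphism, tubule formation, mitotic count)
each take values 1–3; the final grade is 1 for sums 3–5, 2 for 6–7, 3
for 8–9. Binarization maps grades 1–2 → 0 (low/intermediate) and 3 → 1
(high). Auxiliary binary component labels use the per-component analogue
(score 3 vs 1–2).

## Agreement metrics

Cohen's kappa is computed from the marginals as (p_o − p_e)/(1 − p_e).
When both raters use one identical class, agreement is perfect and 1.0
is returned. Bootstrap standard deviations resample slides **jointly**
(paired true/predicted labels), preserving the agreement structure,
which is the only reading under which an agreement metric's bootstrap is
meaningful; degenerate resamples on which the metric is undefined are
redrawn, capped at 10× the replicate count. The default replicate count
is 1000 and the seed is mandatory in the CLI.

## Survival analysis

Three endpoints are built from raw follow-up records:

- **OS** — time to death from any cause, administratively censored at 8
  years (configurable; applied to OS only by default).
- **DRFS** — time to distant recurrence or death; a second primary tumor
  occurring first censors at the second-primary time.
- **RFS** — time to any recurrence (local, regional, distant), with the
  same second-primary censoring.

The Kaplan–Meier product-limit estimator and the two-group log-rank test
are implemented from first principles (vectorized over event times) and
oracle-tested: KM against hand-computed worked sets and the empirical
survivor function in the censoring-free case, log-rank against its
chi-square calibration under the null. Confidence bands use the
Greenwood variance on the complementary log-log scale. Proportional-
hazards fitting delegates to lifelines with Efron tie handling;
stratified fits estimate separate baseline hazards per molecular subtype
(HR/HER2 combination), and categorical covariates are dummy-coded
against explicit reference levels. Schoenfeld-residual diagnostics are
available through the delegated fitter rather than reimplemented.
Significance is two-sided at p < 0.05 throughout.

## The synthetic cohort generator

`SyntheticCohortSpec` describes a cohort of square slides built from a
grid of 224 px tiles. Defaults (a balanced cohort: positive fraction
0.5, motif prevalence 0.2, 25% background, auxiliary-label agreement
0.9, hazard ratio 2.0 at baseline hazard 0.02/year, 8-year horizon)
mirror a high-vs-low/intermediate grading cohort in which roughly half
the slides are high grade and component labels agree strongly with the
overall grade.

Each tile is background (near-white), plain tissue, or a *motif* tile;
motif tiles appear only in positive slides, as a binomial draw at the
motif prevalence over tissue tiles, resampled if zero so every positive
bag contains at least one positive instance (the MIL assumption is
enforced by construction, not just in expectation). Motif tiles carry
many small dark basophilic ellipses; plain tissue carries fewer, larger,
medium-tone blobs. Blob colors, sizes and count distributions are
calibrated so the two classes have near-identical expected mean RGB, and
a per-tile stain jitter is added on top; a logistic classifier on tile
mean color sits near chance (~0.56 cross-validated accuracy). Texture —
the density and size of dark structures — is therefore the only reliable
signal, which is exactly what the MIL loop is supposed to learn.
Auxiliary labels independently equal the grade with the configured
agreement probability. Survival times are exponential with hazard
baseline × HR^grade (the recurrence processes run as proportional
exponentials, distant at 1.2× and local at 0.6× the death hazard, so
recurrence endpoints are somewhat more frequent than death), with a
small grade-independent second-primary process, all administratively
censored at the horizon.

Per-slide random streams are split from the cohort seed, so cohorts are
byte-identical across runs and slide rendering is independent of access
order. Slides are written as single-level tiled TIFFs: synthetic slides
are generated at the working magnification, so no pyramid is needed, and
the tiling module accepts single-level images.

**What the generator does not emulate:** real histology morphology
(nuclei, glands, stroma), stain physics, scanner differences,
multi-resolution pyramids, spatial correlation of tumor regions
(motif tiles are placed independently), and label noise between
pathologists. Passing tests on this cohort demonstrate that the
machinery — selection, optimization, voting, model selection,
calibration of the statistics — behaves correctly under the MIL
assumptions; they do not demonstrate clinical-grade performance on real
slides.

## Problem sizes used in the test suite

The heavy MIL check trains on 80 slides with 10×10 tile grids (motif
prevalence 0.2), 60/20 train/validation, 30 iterations at batch 64, for
three seeds — about 8–9 minutes on one CPU; the log-rank calibration
uses 1000 null and 500 alternative replicates; Cox recovery uses one
5000-record cohort plus 200 replicates of 400 records for CI coverage;
the end-to-end smoke run drives the CLI over a 14-slide cohort. These
sizes were chosen so the whole suite runs comfortably on a laptop while
keeping every statistical bound meaningfully sharp.

## Known limitations

- No deep-learning framework backend is bundled; the production-scale
  ResNet-34 backbone of the original training regime must be plugged in
  through the backbone registry by the user.
- The slide reader handles single-level TIFF/PNG natively; pyramidal
  scanner formats require an external reader plugged behind `SlideInfo`.
- Binary grading only: the low-vs-intermediate distinction (grade 1 vs
  2) is out of scope, as are attention-based MIL aggregators,
  competing-risks survival models and time-varying covariates.
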