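# Methods

This note records the modelling and numerical choices behind `tasksal`,
what the synthetic generator does and does not emulate, and the known
limitations.

## Working frame and coordinates

All computation happens at a canonical 200 × 200 frame.  Images are
resampled bilinearly; gaze coordinates are scaled by
(200/width, 200/height) and floored to pixel indices; bounding boxes
are scaled the same way and expanded to at least 1 × 1 if they would
collapse.  Coordinates are 0-based, `x` is the column, `y` the row, and
boxes are half-open `[xmin, xmax) × [ymin, ymax)`; Pascal-VOC XML
(1-based inclusive) is converted on read.  Gaze samples are used as-is:
no fixation/saccade event detection is applied, so if a source provides
raw samples the maps weight dwell time implicitly.

## Bottom-up conspicuity channels

The colour, intensity and orientation channels follow the classic
center-surround architecture, scaled to the 200 × 200 frame:

* Gaussian pyramid levels 0–6 (level k has side ≈ 200/2^k; level 6 is
  ~3–4 px, the coarsest scale that still carries signal at this frame
  size).  Center levels c ∈ {2, 3}, surround levels s = c + δ with
  δ ∈ {2, 3}, giving four (c, s) pairs per sub-channel.
* Intensity I = (r + g + b)/3.  Colour opponency uses the *linear*
  opponent channels RG = r − g and BY = b − (r + g)/2 rather than
  luminance-normalized ratios.  Linearity makes every center-surround
  difference exactly invariant to adding a constant to all pixels — a
  property we treat as definitional for contrast features — and makes
  the colour channel exactly zero on achromatic images.
* Orientation uses a Gabor bank at 0°, 45°, 90°, 135° with wavelength
  7 px applied at each needed pyramid level; the even (cosine) kernel
  is mean-subtracted so a constant input yields zero energy.  Energy is
  the modulus of the even/odd response pair.
* Each intermediate map m is normalized by the max-promoting operator:
  scale m to [0, 1], find its local maxima (3 × 3 neighbourhood), and
  multiply by (M − m̄)² where M = 1 is the global maximum and m̄ the
  mean of the other local maxima.  Maps with a single dominant peak
  survive; maps with many similar peaks are suppressed.  If there are
  no other local maxima, m̄ = 0.
* Normalized maps are bilinearly upsampled to 200 × 200, summed per
  channel, and the channel is max-normalized to [0, 1].  An all-constant
  channel yields the all-zero map by construction.

All constants (pyramid depth, center levels, deltas, wavelength,
orientations, local-maximum neighbourhood) are exposed in
`ConspicuityConfig`.

## Target and centre features

The target feature encodes *where inside a target the pixel sits*: the
Euclidean distance from the pixel centre to the covering box's centre,
divided by that box's half-diagonal, so the value is 0 at the box
centre and ≈ 1 at its corners; pixels outside every box are 0.  When
boxes overlap, the minimum normalized distance is taken (the most
target-like reading; any covering box may legitimately claim the
pixel).  An inverted encoding (1 − distance inside boxes, peak at the
box centre) is selectable with `invert=True`; the literal distance is
the default.  Both encodings carry the same information up to a sign
inside boxes, and the learned weight flips accordingly, so the choice
does not affect AUCs — only the interpretability of the weight's sign.

The centre feature is the distance from the pixel to the frame centre
(99.5, 99.5) divided by the frame half-diagonal (100√2).  It is a fixed
artifact, byte-identical across calls.  Both features live in [0, 1]
like the conspicuity channels, so the SVM weights are directly
comparable across all five features.

## Ground truth and dataset statistics

* **Fixation maps.**  Sum of isotropic Gaussians centred at the gaze
  pixels, max-normalized.  Default σ = 10 px, roughly one degree of
  visual angle for a 500-px stimulus at a 65 cm viewing distance —
  the usual calibration tolerance of desktop eye trackers — and
  configurable everywhere it is used.  The sum is computed by Gaussian
  filtering of the gaze-count raster (truncation at 4σ, zero-padded
  borders); the far-tail truncation is irrelevant after
  max-normalization.
* **Entropy.**  The average-across-subjects map is normalized to sum to
  one over the 40 000 pixels and Shannon entropy is taken base 2 with
  0·log 0 = 0 (uniform map → log₂ 40000 ≈ 15.29 bits).  The map is
  treated as a probability distribution over *pixels*, not as a
  grey-level histogram; one canonical definition is fixed so that the
  statistic is comparable across analyses.
* **Centre fractions.**  The centre region for area fraction f is the
  axis-aligned rectangle concentric with the frame with linear scale
  √f, so its area is exactly f of the frame; a gaze point counts as
  inside when its pixel centre lies inside the (closed) region.  A
  rectangle, not an ellipse, because the frame is rectangular.
* **Inter-observer model.**  For each subject on an image, the pooled
  fixation map of all *other* subjects predicts that subject's gaze
  pixels; subject AUCs are averaged within the image first, then over
  images per (category, target-present) group.

## Learning

Per training image, 20 positive pixels are sampled uniformly without
replacement from the top 20% quantile of fixation-map values and 20
negatives from the bottom 70% quantile (ties at a threshold are
included in the stratum); the 1:1 ratio keeps the classes balanced and
the strata keep the samples strongly positive/negative.  Features at
the sampled pixels are standardized with train-set statistics only —
test data are transformed with the same parameters, the only
leakage-free reading of a per-fold protocol — and a linear SVM
(L2-regularized hinge loss, C = 1, tol = 1e−6, liblinear with a fixed
seed) is fit per category.  A feature column that is constant in a
training fold (e.g. the target feature when every sampled pixel misses
the boxes) is left unscaled and simply attracts a near-zero weight
instead of aborting the fit; the module-level `standardize` helper, by
contrast, rejects zero-variance columns loudly, since a caller invoking
it directly should know their data are degenerate.

Cross-validation partitions images at random into k = 5 folds,
stratified by category so every fold contains every category.  The
weight report gives per-category mean and population STD of each weight
across folds (or across repeated runs) and the rank order of |mean|.
Prediction maps are min-max normalized decision values; a flat score
field maps to the all-zero map.  One RNG seed fixes sampling, fold
assignment and the solver, making the whole CVResult reproducible
bit-for-bit.

## Evaluation

Positives for the ROC are the pixels containing at least one gaze
point — no threshold on a smoothed human map is needed — and every
other pixel is a negative.  The AUC is the trapezoidal area over the
full threshold sweep, which equals the Mann–Whitney statistic
P(score⁺ > score⁻) + ½ P(equal), so heavily tied maps (e.g. the
all-zero prediction) score exactly 0.5.  Summary tables use the
population STD.  No shuffled-AUC or other centre-bias-corrected metric
is provided: plain AUC is the single metric of record here.

## Synthetic data

The generator emulates the *statistical structure* of a multi-category
visual-search study: 8 categories, 11 subjects, ~59% of each category's
stimuli containing 1–4 non-overlapping target rectangles (20–60 px) in
a category-specific colour on a noisy grey background with 2–5
distractor shapes, and per-subject gaze drawn i.i.d. from a mixture of
(a) a Gaussian (σ = 8 px) around a uniformly chosen target-box centre,
(b) a Gaussian (σ = 30 px) at the frame centre, and (c) a uniform
component, with default weights (0.6, 0.3, 0.1).  On target-absent
images the target weight is redistributed proportionally onto the other
two components.  Out-of-frame draws are resampled (truncation).
Distractors reuse the target colours of *other* categories, so
bottom-up conspicuity is informative but not sufficient and the target
feature's contribution is measurable.  Scenes and gaze are generated
from separate child streams of the master seed, so changing the gaze
mixture leaves the images untouched.

What the generator does **not** emulate: photorealistic scene content,
saccade dynamics and scan-path order, subject idiosyncrasies, dwell
time, or any correlation between target size and gaze spread.  Tests
passing on this data therefore validate the pipeline's mechanics and
its statistical behaviour under a known generative model — not
performance on natural images.

## Experiment sizes used by the reproduction script

`scripts/acceptance.py` runs the dataset statistics at the generator's
default scale (8 × 10 images, 11 subjects, 20 gaze points per subject
per image), the sampling-stage count over 160 ground-truth maps at
20 + 20 samples each, and the model experiments on 8 × 10
target-present images with 5 subjects and 50 gaze points per subject,
target-dominated mixture (0.9, 0.05, 0.05) — sizes at which the
experiments are informative while a full run completes in well under a
minute on a laptop.  Weight-recovery and ablation experiments use
target-present stimuli only, since the target weight is identified only
on images that contain targets.

## Known limitations

* The conspicuity recipe is one reasonable scaling of the classic
  architecture to a 200 × 200 frame; pyramid depth and Gabor
  parameters materially change the low-level maps, and no claim is made
  that this instantiation matches any particular published
  implementation constant-for-constant.
* The target feature requires bounding-box annotations at prediction
  time; the model predicts *task-oriented* saliency only where the
  task's target locations are known or proposed by an upstream
  detector.
* Original-resolution analysis is unsupported by design; all statistics
  inherit the 200 × 200 discretization.
* With the literal distance encoding the target weight's *sign* is hard
  to interpret in isolation (large values sit at box corners); use the
  inverted encoding when the sign matters for interpretation.
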