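# tasksal — task-oriented visual saliency

`tasksal` models where people look when they search an image for a
particular object category, rather than when they free-view it.  It is
aimed at researchers in visual attention and eye tracking who want a
compact, fully testable implementation of a gaze-trained saliency
pipeline: feature extraction, ground-truth construction from gaze
points, linear model training, and ROC/AUC evaluation — plus a
synthetic scene-and-gaze generator so every stage runs without access
to an eye tracker.

## The model

Every image is analysed on a canonical 200 × 200 frame.  Five per-pixel
feature maps are computed, each max-normalized to [0, 1]:

* **color, intensity, orientation** — bottom-up conspicuity from a
  center-surround pyramid architecture: across-scale differences
  |F(c) − F(s)| between fine (c ∈ {2, 3}) and coarse (s = c + δ,
  δ ∈ {2, 3}) Gaussian-pyramid levels of the luminance, the opponent
  colour channels, and a 4-orientation Gabor bank, each intermediate
  map passed through a max-promoting normalization before summation;
* **target** — for each pixel inside an annotated target bounding box,
  the distance to that box's centre normalized by its half-diagonal
  (0 outside all boxes); this is the task-dependent feature;
* **center** — the distance of the pixel to the frame centre normalized
  by the frame half-diagonal (the centre-bias prior).

Ground truth for an image is a fixation map: a sum of isotropic
Gaussians (σ = 10 px by default) centred at the recorded gaze points.
Per image, 20 *positive* pixels are sampled from the top 20% of the
fixation map and 20 *negatives* from the bottom 70%.  The feature
vectors **x** ∈ ℝ⁵ at those pixels, standardized to zero mean and unit
variance, train a linear SVM per category:

    f(x) = wᵀ (x − μ) / σ + b

minimizing the L2-regularized hinge loss.  The saliency map of a new
image is the decision value per pixel, min-max normalized.  Maps are
scored as per-pixel classifiers of fixated vs non-fixated pixels; the
area under the ROC curve (AUC, equal to the Mann–Whitney statistic) is
the headline metric, reported as per-category mean ± STD over 5-fold
cross-validation.  The inter-observer (IO) model — predicting one
subject's fixations from everyone else's — gives the consistency
ceiling, and an ablation without the target feature quantifies how much
the task contributes.

## Worked example

```python
import numpy as np
from tasksal import SyntheticConfig, generate_dataset, io_consistency
from tasksal.learning import compute_stacks, cross_validate, weight_report

cfg = SyntheticConfig(n_images_per_category=10, categories=("car", "dog"),
                      n_subjects=5, n_gaze_per_subject_per_image=50,
                      target_present_fraction=1.0, mix=(0.9, 0.05, 0.05), seed=1)
dataset = generate_dataset(cfg)
stacks = compute_stacks(dataset)
result = cross_validate(dataset, k=5, rng=np.random.default_rng(1), stacks=stacks)
print(f"mean cross-validated AUC: {result.mean_auc:.4f} (STD {result.std_auc:.4f})")
```

prints

```
mean cross-validated AUC: 0.8711 (STD 0.0176)
```

meaning the learned five-feature model separates fixated from
non-fixated pixels far above chance (0.5) on held-out images.  With
gaze simulated 90% from target locations, the weight report shows the
target weight consistently positive and large, and `io_consistency`
puts the between-subject ceiling near 0.93–0.94:

```
category  target_present  avg_auc  std_auc  n_images
     car            True    0.940    0.012        10
     dog            True    0.928    0.014        10
```

## Command line

The same workflow as a console tool, each stage reproducible from one
master seed:

```sh
tasksal simulate --out data --seed 7
tasksal train    --dataset data --out models --seed 7
tasksal predict  --dataset data --models models --out maps
tasksal evaluate --dataset data --models models --out eval
tasksal analyze  --dataset data --out stats
```

`simulate` writes PNG images, a gaze CSV, a box CSV and a manifest;
`train` writes per-category model files, a weight report (per-category
Avg/STD of each weight) and per-fold AUCs; `analyze` writes entropy,
centre-fraction, target-hit, gaze-count and IO-consistency tables.

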