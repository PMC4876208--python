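"""Synthetic visual-search stimuli and multi-subject gaze.

Emulates the statistical structure of a task-oriented eye-tracking
study: images grouped into search categories, each image either
target-present (one or more annotated target rectangles in a
category-specific colour) or target-absent, and per-subject gaze points
drawn from a three-part mixture of target-centred, image-centre-biased
and uniform components.  Distractor shapes reuse the target colours of
*other* categories, so bottom-up conspicuity alone cannot identify the
target — the target-location feature has to earn its weight.

All randomness flows from a single seed via independent child streams
for scenes and gaze, so the same seed regenerates byte-identical data
(and the same scenes regardless of the gaze mixture settings).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (
    CANONICAL_SIZE,
    BoundingBox,
    ContractError,
    Dataset,
    GazePoint,
    ImageRecord,
)

__all__ = ["SyntheticConfig", "generate_scene", "simulate_gaze", "generate_dataset"]

#: Category palette: one saturated fill colour per search category.
_PALETTE = {
    "airplane": (200, 205, 215),
    "bottle": (40, 160, 60),
    "car": (200, 40, 40),
    "chair": (150, 100, 50),
    "dog": (220, 180, 130),
    "horse": (110, 70, 40),
    "motorbike": (50, 50, 180),
    "person": (230, 190, 160),
}

_FALLBACK_COLORS = [
    (210, 90, 150), (90, 200, 200), (240, 220, 60), (120, 60, 170),
]

DEFAULT_CATEGORIES = tuple(_PALETTE)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    The defaults mirror a desk-scale version of a multi-category visual
    search study: 8 categories, 11 subjects, about 59% of the stimuli in
    each group containing the target, gaze dominated by the target
    (mixture weight 0.6) with a centre-bias component (0.3) and a small
    uniform remainder (0.1).  ``sigma_target``/``sigma_center`` are the
    standard deviations (canonical pixels) of the Gaussian spread around
    a target-box centre and the frame centre.
    """

    n_images_per_category: int = 10
    categories: tuple = DEFAULT_CATEGORIES
    target_present_fraction: float = 0.59
    n_subjects: int = 11
    n_gaze_per_subject_per_image: int = 20
    mix: tuple = (0.6, 0.3, 0.1)  # (p_target, p_center, p_uniform)
    sigma_target: float = 8.0
    sigma_center: float = 30.0
    n_targets_range: tuple = (1, 4)
    box_size_range: tuple = (20, 60)
    n_distractors_range: tuple = (2, 5)
    noise_amplitude: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mix, dtype=float)
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ContractError(f"mixture weights {self.mix} must be >=0 and sum to 1")
        if not (0 <= self.target_present_fraction <= 1):
            raise ContractError("target_present_fraction outside [0, 1]")
        lo, hi = self.n_targets_range
        if not (1 <= lo <= hi):
            raise ContractError(f"invalid n_targets_range {self.n_targets_range}")
        lo, hi = self.box_size_range
        if not (2 <= lo <= hi <= CANONICAL_SIZE):
            raise ContractError(f"invalid box_size_range {self.box_size_range}")


def _category_color(category: str, categories) -> tuple:
    if category in _PALETTE:
        return _PALETTE[category]
    extra = [c for c in categories if c not in _PALETTE]
    return _FALLBACK_COLORS[extra.index(category) % len(_FALLBACK_COLORS)]


def _place_boxes(rng: np.random.Generator, n_boxes: int, size_range, label: str,
                 avoid: list, max_attempts: int = 1000) -> list[BoundingBox]:
    placed: list[BoundingBox] = []
    n = CANONICAL_SIZE
    for _ in range(n_boxes):
        for attempt in range(max_attempts):
            w = int(rng.integers(size_range[0], size_range[1] + 1))
            h = int(rng.integers(size_range[0], size_range[1] + 1))
            x0 = int(rng.integers(0, n - w + 1))
            y0 = int(rng.integers(0, n - h + 1))
            box = BoundingBox(xmin=x0, ymin=y0, xmax=x0 + w, ymax=y0 + h, label=label)
            overlap = any(
                box.xmin < o.xmax and o.xmin < box.xmax
                and box.ymin < o.ymax and o.ymin < box.ymax
                for o in placed + avoid
            )
            if not overlap:
                placed.append(box)
                break
        else:
            raise ContractError(
                f"could not place {n_boxes} non-overlapping boxes "
                f"after {max_attempts} attempts")
    return placed


def _paint(pixels: np.ndarray, box: BoundingBox, color, rng, shape: str) -> None:
    y0, y1 = int(box.ymin), int(box.ymax)
    x0, x1 = int(box.xmin), int(box.xmax)
    region = pixels[y0:y1, x0:x1]
    if shape == "ellipse":
        h, w = region.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        mask = (((xx - (w - 1) / 2) / (w / 2)) ** 2
                + ((yy - (h - 1) / 2) / (h / 2)) ** 2) <= 1.0
    else:
        mask = np.ones(region.shape[:2], dtype=bool)
    for ch in range(3):
        region[..., ch][mask] = color[ch]


def generate_scene(
    config: SyntheticConfig, category: str, target_present: bool,
    rng: np.random.Generator, image_id: str = "img",
) -> tuple[ImageRecord, list[BoundingBox]]:
    """One 200x200 stimulus: noisy grey background, 2-5 distractor
    shapes coloured like other categories' targets, and (if
    target-present) 1-4 non-overlapping target rectangles in the
    category colour, each recorded as a bounding box."""
    n = CANONICAL_SIZE
    base = 128.0 + config.noise_amplitude * rng.standard_normal((n, n, 1))
    pixels = np.clip(np.repeat(base, 3, axis=2), 0, 255)

    target_boxes: list[BoundingBox] = []
    if target_present:
        k = int(rng.integers(config.n_targets_range[0],
                             config.n_targets_range[1] + 1))
        target_boxes = _place_boxes(rng, k, config.box_size_range, category, [])

    n_distr = int(rng.integers(config.n_distractors_range[0],
                               config.n_distractors_range[1] + 1))
    others = [c for c in config.categories if c != category] or [category]
    distractors = _place_boxes(rng, n_distr, config.box_size_range,
                               "distractor", avoid=target_boxes)
    for d in distractors:
        other = others[int(rng.integers(len(others)))]
        shape = "ellipse" if rng.random() < 0.5 else "rect"
        _paint(pixels, d, _category_color(other, config.categories), rng, shape)
    color = _category_color(category, config.categories)
    for b in target_boxes:
        _paint(pixels, b, color, rng, "rect")

    image = ImageRecord(id=image_id, pixels=pixels, category=category,
                        target_present=bool(target_boxes))
    return image, target_boxes


def _sample_mixture_point(rng, mix, boxes, sigma_target, sigma_center):
    n = CANONICAL_SIZE
    p_target, p_center, p_uniform = mix
    if not boxes and p_target > 0:
        # no target to look at: reassign its weight evenly to the others
        rest = p_center + p_uniform
        if rest <= 0:
            p_center = p_uniform = 0.5
        else:
            p_center += p_target * (p_center / rest)
            p_uniform += p_target * (p_uniform / rest)
        p_target = 0.0
    while True:
        u = rng.random()
        if u < p_target:
            box = boxes[int(rng.integers(len(boxes)))]
            cx, cy = box.center
            x = rng.normal(cx, sigma_target)
            y = rng.normal(cy, sigma_target)
        elif u < p_target + p_center:
            x = rng.normal(n / 2.0, sigma_center)
            y = rng.normal(n / 2.0, sigma_center)
        else:
            x = rng.uniform(0, n)
            y = rng.uniform(0, n)
        if 0 <= x < n and 0 <= y < n:
            return float(x), float(y)


def simulate_gaze(
    image: ImageRecord, boxes, config: SyntheticConfig, rng: np.random.Generator,
) -> list[GazePoint]:
    """Per-subject gaze points from the target/centre/uniform mixture.

    Points falling outside the frame are resampled (truncation).  When
    the image has no boxes, the target weight is redistributed
    proportionally onto the centre and uniform components.
    """
    points = []
    for s in range(config.n_subjects):
        subject = f"s{s:02d}"
        for _ in range(config.n_gaze_per_subject_per_image):
            x, y = _sample_mixture_point(
                rng, config.mix, list(boxes), config.sigma_target,
                config.sigma_center)
            points.append(GazePoint(subject=subject, image_id=image.id, x=x, y=y))
    return points


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """A full reproducible dataset: per-category target-present and
    target-absent stimuli with boxes and multi-subject gaze."""
    root = np.random.SeedSequence(config.seed)
    scene_seed, gaze_seed = root.spawn(2)
    scene_rngs = [np.random.default_rng(s) for s in scene_seed.spawn(
        len(config.categories) * config.n_images_per_category)]
    gaze_rngs = [np.random.default_rng(s) for s in gaze_seed.spawn(
        len(config.categories) * config.n_images_per_category)]

    dataset = Dataset()
    idx = 0
    for category in config.categories:
        n_present = int(round(config.target_present_fraction
                              * config.n_images_per_category))
        for i in range(config.n_images_per_category):
            target_present = i < n_present
            image_id = f"{category}_{i:03d}"
            image, boxes = generate_scene(
                config, category, target_present, scene_rngs[idx],
                image_id=image_id)
            gaze = simulate_gaze(image, boxes, config, gaze_rngs[idx])
            dataset.images.append(image)
            dataset.boxes[image_id] = boxes
            dataset.gaze.extend(gaze)
            idx += 1
    dataset.validate()
    return dataset
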