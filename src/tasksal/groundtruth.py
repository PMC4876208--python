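"""Continuous fixation maps and dataset-level gaze statistics.

A fixation map is the sum of isotropic Gaussians centred at each gaze
point, max-normalized to [0, 1].  The statistics quantify properties of
a gaze dataset: spatial spread (entropy of the average map), centre
bias (fraction of gaze inside concentric centre regions), how often
gaze lands on the target, inter-observer maps, and per-group gaze
counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import entropy as _shannon_entropy

from .datatypes import (
    CANONICAL_SIZE,
    BoundingBox,
    ContractError,
    Dataset,
    GazePoint,
)

__all__ = [
    "fixation_map",
    "average_subject_map",
    "map_entropy",
    "center_fraction_stats",
    "target_hit_stats",
    "interobserver_map",
    "gaze_count_summary",
]

#: Default smoothing for fixation maps, in canonical pixels.  Roughly one
#: degree of visual angle for a 500-px stimulus viewed at 65 cm, matching
#: the common calibration tolerance of desktop eye trackers.
DEFAULT_SIGMA = 10.0


def fixation_map(gaze_points: Sequence[GazePoint], sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Continuous saliency map from gaze points.

    Sum of isotropic Gaussians of standard deviation ``sigma`` centred
    at each gaze point's pixel, max-normalized to [0, 1].  An empty gaze
    list yields the all-zero map.
    """
    if sigma <= 0:
        raise ContractError(f"sigma must be positive, got {sigma}")
    n = CANONICAL_SIZE
    counts = np.zeros((n, n))
    for g in gaze_points:
        x, y = int(g.x), int(g.y)
        if not (0 <= x < n and 0 <= y < n):
            raise ContractError(f"gaze point ({g.x}, {g.y}) outside canonical frame")
        counts[y, x] += 1.0
    if counts.max() == 0:
        return counts
    smoothed = gaussian_filter(counts, sigma=sigma, mode="constant")
    return smoothed / smoothed.max()


def average_subject_map(per_subject_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise mean of per-subject maps, re-max-normalized."""
    if len(per_subject_maps) == 0:
        raise ContractError("average_subject_map needs at least one map")
    mean = np.mean([np.asarray(m, dtype=float) for m in per_subject_maps], axis=0)
    top = mean.max()
    return mean / top if top > 0 else mean


def map_entropy(values: np.ndarray) -> float:
    """Shannon entropy (bits) of a map treated as a distribution over pixels.

    The map is normalized to sum to one; ``0 log 0 = 0``.  The uniform
    200x200 map gives ``log2(40000)`` ~ 15.29 bits, a point mass gives 0.
    """
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ContractError("map_entropy requires a non-zero map")
    return float(_shannon_entropy(values.ravel() / total, base=2))


def center_fraction_stats(
    gaze_points: Sequence[GazePoint], fractions: Sequence[float] = (0.02, 0.11, 0.25, 0.65)
) -> dict[float, float]:
    """Percent of gaze points inside concentric centre regions.

    For each area fraction ``f`` the region is the axis-aligned
    rectangle concentric with the frame with the frame's aspect ratio
    and linear scale ``sqrt(f)`` (area exactly ``f``); a point counts as
    inside when its pixel centre lies inside the region.
    """
    if len(gaze_points) == 0:
        raise ContractError("center_fraction_stats requires gaze points")
    for f in fractions:
        if not (0 < f <= 1):
            raise ContractError(f"area fraction {f} outside (0, 1]")
    n = CANONICAL_SIZE
    cx = cy = n / 2.0
    px = np.array([int(g.x) + 0.5 for g in gaze_points])
    py = np.array([int(g.y) + 0.5 for g in gaze_points])
    out = {}
    for f in fractions:
        half = (n * np.sqrt(f)) / 2.0
        inside = (
            (px >= cx - half) & (px <= cx + half)
            & (py >= cy - half) & (py <= cy + half)
        )
        out[float(f)] = 100.0 * inside.mean()
    return out


def target_hit_stats(
    gaze_points: Sequence[GazePoint], boxes: Sequence[BoundingBox]
) -> float:
    """Percent of gaze points whose pixel lies inside any target box."""
    if len(gaze_points) == 0:
        raise ContractError("target_hit_stats requires gaze points")
    if not boxes:
        return 0.0
    hits = sum(
        1
        for g in gaze_points
        if any(b.contains(int(g.x) + 0.5, int(g.y) + 0.5) for b in boxes)
    )
    return 100.0 * hits / len(gaze_points)


def interobserver_map(
    dataset: Dataset, image_id: str, excluded_subject: str, sigma: float = DEFAULT_SIGMA
) -> np.ndarray:
    """Fixation map pooled over all subjects except the one under test."""
    subjects = dataset.subjects_on(image_id)
    if len(subjects) < 2:
        raise ContractError(
            f"interobserver map for {image_id!r} needs >= 2 subjects, "
            f"found {len(subjects)}"
        )
    pooled = [
        g for g in dataset.gaze
        if g.image_id == image_id and g.subject != excluded_subject
    ]
    return fixation_map(pooled, sigma=sigma)


def gaze_count_summary(dataset: Dataset) -> pd.DataFrame:
    """Mean gaze count per stimulus, grouped by category x target-present.

    Images with zero gaze contribute zero to their group's mean.  Groups
    with no images are absent from the output.
    """
    counts = {}
    for g in dataset.gaze:
        counts[g.image_id] = counts.get(g.image_id, 0) + 1
    rows = [
        {
            "category": im.category,
            "target_present": bool(im.target_present),
            "n_gaze": counts.get(im.id, 0),
        }
        for im in dataset.images
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["category", "target_present", "mean_gaze_count", "n_images"]
        )
    out = (
        df.groupby(["category", "target_present"], as_index=False)
        .agg(mean_gaze_count=("n_gaze", "mean"), n_images=("n_gaze", "size"))
        .sort_values(["category", "target_present"])
        .reset_index(drop=True)
    )
    return out
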