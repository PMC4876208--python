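"""ROC/AUC scoring of saliency maps against gaze, and its aggregates.

A saliency map is treated as a per-pixel classifier of fixated versus
non-fixated pixels: the positives are the pixels containing at least
one gaze point, every other pixel is a negative, and the threshold on
the map value is swept to trace the ROC curve.  The AUC equals the
Mann-Whitney statistic P(score_pos > score_neg) + 1/2 P(equal), so tied
map values are handled without bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics

from .datatypes import CANONICAL_SIZE, ContractError, Dataset, GazePoint
from .groundtruth import DEFAULT_SIGMA, interobserver_map

__all__ = ["RocCurve", "roc_curve", "auc", "gaze_to_pixels",
           "evaluate_dataset", "io_consistency"]

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    """An ROC curve: thresholds in descending order with the false- and
    true-positive rates attained at each."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


def gaze_to_pixels(gaze_points: Sequence[GazePoint]) -> np.ndarray:
    """Boolean 200x200 mask of pixels containing at least one gaze point."""
    n = CANONICAL_SIZE
    mask = np.zeros((n, n), dtype=bool)
    for g in gaze_points:
        x, y = int(g.x), int(g.y)
        if not (0 <= x < n and 0 <= y < n):
            raise ContractError(f"gaze point ({g.x}, {g.y}) outside canonical frame")
        mask[y, x] = True
    return mask


def _validate_positives(pred_map: np.ndarray, positive_pixels: np.ndarray):
    pred = np.asarray(pred_map, dtype=float)
    pos = np.asarray(positive_pixels)
    if pos.dtype != bool:
        pos = pos.astype(bool)
    if pred.shape != pos.shape:
        raise ContractError(
            f"prediction shape {pred.shape} != positive mask shape {pos.shape}"
        )
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ContractError("no positive pixels (no gaze on the image)")
    if n_pos == pos.size:
        raise ContractError("all pixels positive; ROC undefined")
    return pred, pos


def roc_curve(pred_map: np.ndarray, positive_pixels: np.ndarray) -> RocCurve:
    """ROC of a predicted map against a boolean fixated-pixel mask.

    Thresholds are swept over the distinct predicted values; the curve
    always includes the endpoints (0, 0) and (1, 1).
    """
    pred, pos = _validate_positives(pred_map, positive_pixels)
    fpr, tpr, thr = _skmetrics.roc_curve(
        pos.ravel().astype(int), pred.ravel(), drop_intermediate=False
    )
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc(pred_map: np.ndarray, positive_pixels: np.ndarray) -> float:
    """Area under the ROC curve (trapezoidal; equals the Mann-Whitney
    statistic with ties counted half)."""
    curve = roc_curve(pred_map, positive_pixels)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def evaluate_dataset(
    models: Mapping[str, "LinearGazeSaliency"],
    dataset: Dataset,
    sigma: float = DEFAULT_SIGMA,
    stacks: Mapping[str, "FeatureStack"] | None = None,
) -> pd.DataFrame:
    """Per-image AUC of each category model's prediction against that
    image's gaze pixels, aggregated to per-category Avg and STD
    (population STD), categories in alphabetical order.

    ``stacks`` maps image_id to a precomputed feature stack; if omitted
    the stacks are computed on the fly from the dataset images/boxes.
    Images without gaze are skipped with a warning.
    """
    from .features import build_feature_stack  # local import to avoid cycle

    per_image = []
    for im in dataset.images:
        gaze = dataset.gaze_for(im.id)
        if not gaze:
            logger.warning("image %s has no gaze; skipped", im.id)
            continue
        model = models[im.category]
        stack = stacks[im.id] if stacks is not None else build_feature_stack(
            im, dataset.boxes_for(im.id)
        )
        pred = model.predict_map(stack)
        per_image.append(
            {"image_id": im.id, "category": im.category,
             "auc": auc(pred, gaze_to_pixels(gaze))}
        )
    df = pd.DataFrame(per_image)
    if df.empty:
        raise ContractError("no image in the dataset has gaze")
    summary = (
        df.groupby("category")["auc"]
        .agg(avg_auc="mean", std_auc=lambda s: float(np.std(s)), n_images="size")
        .reset_index()
        .sort_values("category")
        .reset_index(drop=True)
    )
    summary.attrs["per_image"] = df
    return summary


def io_consistency(dataset: Dataset, sigma: float = DEFAULT_SIGMA) -> pd.DataFrame:
    """Inter-observer consistency, the ceiling any model can aim for.

    For every image and every subject with gaze on it: the AUC of the
    pooled other-subject fixation map against that subject's gaze
    pixels.  Subject AUCs are averaged within each image first, then
    image scores are averaged per (category, target-present) group.
    Images seen by fewer than two subjects are skipped with a warning.
    """
    rows = []
    for im in dataset.images:
        subjects = dataset.subjects_on(im.id)
        if len(subjects) < 2:
            if subjects:
                logger.warning("image %s has a single subject; skipped", im.id)
            continue
        subject_aucs = []
        for subj in subjects:
            io_map = interobserver_map(dataset, im.id, subj, sigma=sigma)
            own = gaze_to_pixels(dataset.gaze_for(im.id, subj))
            if io_map.max() == 0:
                continue
            subject_aucs.append(auc(io_map, own))
        if subject_aucs:
            rows.append(
                {"category": im.category, "target_present": bool(im.target_present),
                 "auc": float(np.mean(subject_aucs))}
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ContractError("no image has gaze from >= 2 subjects")
    out = (
        df.groupby(["category", "target_present"], as_index=False)
        .agg(avg_auc=("auc", "mean"),
             std_auc=("auc", lambda s: float(np.std(s))),
             n_images=("auc", "size"))
        .sort_values(["category", "target_present"])
        .reset_index(drop=True)
    )
    return out
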