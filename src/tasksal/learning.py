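"""Learning the per-category saliency model from gaze.

The pipeline mirrors the experimental procedure: per image, build a
ground-truth fixation map, sample positive pixels from the top 20%
salient locations and negatives from the bottom 70% (20 each, a 1:1
class balance), look up the five feature values at each sampled pixel,
standardize to zero mean / unit variance with train-set statistics, and
fit a linear max-margin classifier.  The learned weights per feature
are directly comparable because every feature map is max-normalized
before sampling.

The core is :class:`LinearGazeSaliency`, a scikit-learn style estimator
(``fit`` / ``predict`` / ``decision_function`` / ``predict_map``); the
module-level functions are thin wrappers matching the procedural
workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .datatypes import (
    CANONICAL_SIZE,
    FEATURE_NAMES,
    ContractError,
    Dataset,
    FeatureStack,
)
from .evaluation import auc, gaze_to_pixels
from .features import ConspicuityConfig, DEFAULT_CONSPICUITY, build_feature_stack
from .groundtruth import DEFAULT_SIGMA, fixation_map

__all__ = [
    "LinearGazeSaliency",
    "TrainingSet",
    "CVResult",
    "sample_training_pixels",
    "assemble_training_set",
    "standardize",
    "train_linear_svm",
    "predict_saliency",
    "cross_validate",
    "weight_report",
    "save_model",
    "load_model",
]


@dataclass
class TrainingSet:
    """Balanced pixel-level training data.

    ``X`` is N x n_features, ``y`` is in {+1, -1}, and ``provenance``
    records (image_id, x, y) per row.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: list = field(default_factory=list)
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ContractError("X and y shapes inconsistent")
        if not np.all(np.isfinite(self.X)):
            raise ContractError("training set contains non-finite features")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ContractError("labels must be in {+1, -1}")


def sample_training_pixels(
    truth_map: np.ndarray,
    n_pos: int = 20,
    n_neg: int = 20,
    top_frac: float = 0.20,
    bottom_frac: float = 0.70,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[int, int, int]]:
    """Sample labelled pixels from a ground-truth map.

    Positives are drawn uniformly without replacement from the top
    ``top_frac`` quantile of map values, negatives from the bottom
    ``bottom_frac`` quantile; ties at a threshold are included in the
    stratum.  Returns ``(x, y, label)`` triples with label +1/-1.
    """
    rng = np.random.default_rng(rng)
    vals = np.asarray(truth_map, dtype=float)
    if vals.max() <= 0:
        raise ContractError("sample_training_pixels requires a non-zero map")
    flat = vals.ravel()
    hi_thr = np.quantile(flat, 1.0 - top_frac)
    lo_thr = np.quantile(flat, bottom_frac)
    top_idx = np.flatnonzero(flat >= hi_thr)
    bot_idx = np.flatnonzero(flat <= lo_thr)
    if top_idx.size < n_pos:
        raise ContractError(
            f"top stratum has {top_idx.size} pixels, need {n_pos}")
    if bot_idx.size < n_neg:
        raise ContractError(
            f"bottom stratum has {bot_idx.size} pixels, need {n_neg}")
    pos = rng.choice(top_idx, size=n_pos, replace=False)
    neg = rng.choice(bot_idx, size=n_neg, replace=False)
    w = vals.shape[1]
    out = [(int(i % w), int(i // w), +1) for i in pos]
    out += [(int(i % w), int(i // w), -1) for i in neg]
    return out


def assemble_training_set(
    stacks: Mapping[str, FeatureStack],
    samples: Mapping[str, Sequence[tuple[int, int, int]]],
    feature_subset: Optional[Sequence[str]] = None,
) -> TrainingSet:
    """Look up feature values at sampled pixels across images.

    ``samples`` maps image_id to (x, y, label) triples; every image_id
    must resolve to a feature stack.  ``feature_subset`` restricts the
    columns (used for ablations); default is all five features.
    """
    names = tuple(feature_subset) if feature_subset else FEATURE_NAMES
    rows, labels, prov = [], [], []
    for image_id, triples in samples.items():
        if image_id not in stacks:
            raise ContractError(f"no feature stack for image {image_id!r}")
        arrs = [stacks[image_id][nm].values for nm in names]
        for x, y, lab in triples:
            rows.append([a[y, x] for a in arrs])
            labels.append(lab)
            prov.append((image_id, x, y))
    ts = TrainingSet(X=np.array(rows, dtype=float), y=np.array(labels),
                     provenance=prov, feature_names=names)
    return ts


def standardize(
    train: TrainingSet, other: Optional[TrainingSet] = None
) -> tuple:
    """Zero-mean unit-variance scaling fit on the train set only.

    Returns ``(train_std, other_std, means, sds)``; ``other`` (e.g. the
    test set) is transformed with the train statistics.
    """
    means = train.X.mean(axis=0)
    sds = train.X.std(axis=0)
    zero = np.flatnonzero(sds <= 0)
    if zero.size:
        bad = [train.feature_names[i] for i in zero]
        raise ContractError(f"zero-variance feature(s): {bad}")
    def _apply(ts: TrainingSet) -> TrainingSet:
        return TrainingSet(X=(ts.X - means) / sds, y=ts.y,
                           provenance=list(ts.provenance),
                           feature_names=ts.feature_names)
    return _apply(train), (_apply(other) if other is not None else None), means, sds


class LinearGazeSaliency(BaseEstimator, ClassifierMixin):
    """Linear max-margin saliency classifier over per-pixel features.

    Standardizes the features with train-set statistics and fits an
    L2-regularized hinge-loss linear SVM; the signed decision value over
    a full feature stack, min-max normalized, is the predicted saliency
    map.

    Parameters
    ----------
    C : float
        Inverse regularization strength of the SVM.
    tol : float
        Optimizer stopping tolerance.
    feature_names : tuple of str
        Names of the feature columns, in order (supports ablations).
    category : str
        Tag for the search category this model belongs to.
    random_state : int
        Seed for the underlying solver (results are deterministic for a
        fixed value).

    Attributes
    ----------
    weights_ : ndarray, shape (n_features,)
        Learned weight per feature, on the standardized scale.
    bias_ : float
        Intercept of the decision function.
    feature_means_, feature_sds_ : ndarray
        Standardization statistics from the training set.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-6,
                 feature_names: tuple = FEATURE_NAMES,
                 category: str = "", random_state: int = 0,
                 max_iter: int = 100000):
        self.C = C
        self.tol = tol
        self.feature_names = feature_names
        self.category = category
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ContractError("X must be 2-D")
        classes = np.unique(y)
        if classes.size < 2:
            raise ContractError("training data must contain both classes")
        if not set(classes) <= {-1, 1}:
            raise ContractError("labels must be in {+1, -1}")
        self.feature_means_ = X.mean(axis=0)
        self.feature_sds_ = X.std(axis=0)
        # a constant column carries no information; leave it unscaled so
        # it simply attracts a (near-)zero weight instead of failing the
        # whole fit (e.g. the target feature on all-target-absent folds)
        self.feature_sds_ = np.where(self.feature_sds_ <= 0, 1.0,
                                     self.feature_sds_)
        Xs = (X - self.feature_means_) / self.feature_sds_
        svm = LinearSVC(C=self.C, loss="hinge", tol=self.tol,
                        max_iter=self.max_iter, random_state=self.random_state)
        svm.fit(Xs, y)
        self.weights_ = svm.coef_.ravel().copy()
        self.bias_ = float(svm.intercept_[0])
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.feature_means_) / self.feature_sds_
        return Xs @ self.weights_ + self.bias_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def predict_map(self, stack: FeatureStack) -> np.ndarray:
        """Saliency map for a full feature stack: per-pixel decision
        values min-max normalized to [0, 1] (a flat score field maps to
        the all-zero map)."""
        check_is_fitted(self, "weights_")
        arr = np.stack([stack[nm].values for nm in self.feature_names], axis=-1)
        score = self.decision_function(arr.reshape(-1, arr.shape[-1]))
        score = score.reshape(arr.shape[:2])
        lo, hi = score.min(), score.max()
        if hi - lo <= 1e-12:
            return np.zeros_like(score)
        return (score - lo) / (hi - lo)


def train_linear_svm(
    ts: TrainingSet, C: float = 1.0, tol: float = 1e-6,
    rng: Optional[int] = None, category: str = "",
) -> LinearGazeSaliency:
    """Fit a :class:`LinearGazeSaliency` on a training set."""
    seed = int(rng) if rng is not None else 0
    model = LinearGazeSaliency(C=C, tol=tol, feature_names=ts.feature_names,
                               category=category, random_state=seed % (2**31))
    return model.fit(ts.X, ts.y)


def predict_saliency(model: LinearGazeSaliency, stack: FeatureStack) -> np.ndarray:
    """Module-level alias for :meth:`LinearGazeSaliency.predict_map`."""
    return model.predict_map(stack)


@dataclass
class CVResult:
    """Cross-validation output: per-fold category models and AUCs."""

    folds: list  # list of lists of image ids (test fold membership)
    models: list  # list of dicts category -> LinearGazeSaliency
    fold_aucs: list  # mean per-image AUC of each held-out fold
    mean_auc: float
    std_auc: float  # population STD over folds
    weights: pd.DataFrame  # rows: fold x category, columns: feature weights

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold": np.arange(len(self.fold_aucs)), "auc": self.fold_aucs}
        )


def _per_image_truth_samples(
    dataset: Dataset, image_ids, sigma, n_pos, n_neg, top_frac, bottom_frac, rng
):
    samples = {}
    for image_id in image_ids:
        gaze = dataset.gaze_for(image_id)
        if not gaze:
            continue
        truth = fixation_map(gaze, sigma=sigma)
        samples[image_id] = sample_training_pixels(
            truth, n_pos=n_pos, n_neg=n_neg, top_frac=top_frac,
            bottom_frac=bottom_frac, rng=rng)
    return samples


def compute_stacks(
    dataset: Dataset,
    config: ConspicuityConfig = DEFAULT_CONSPICUITY,
    invert_target: bool = False,
) -> dict[str, FeatureStack]:
    """Feature stacks for every image in a dataset (the expensive step;
    compute once and reuse across folds/models)."""
    return {
        im.id: build_feature_stack(im, dataset.boxes_for(im.id), config=config,
                                   invert_target=invert_target)
        for im in dataset.images
    }


def cross_validate(
    dataset: Dataset,
    k: int = 5,
    sigma: float = DEFAULT_SIGMA,
    C: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    n_pos: int = 20,
    n_neg: int = 20,
    top_frac: float = 0.20,
    bottom_frac: float = 0.70,
    feature_subset: Optional[Sequence[str]] = None,
    stacks: Optional[Mapping[str, FeatureStack]] = None,
) -> CVResult:
    """k-fold cross-validation of per-category models.

    Images are partitioned at random into k folds, stratified by
    category so each fold sees every category.  For each fold, one
    model per category is trained on the remaining images and every
    held-out image is scored by its category's model (AUC against the
    held-out gaze pixels).
    """
    rng = np.random.default_rng(rng)
    dataset.validate()
    by_cat: dict[str, list[str]] = {}
    for im in dataset.images:
        by_cat.setdefault(im.category, []).append(im.id)
    for cat, ids in sorted(by_cat.items()):
        if len(ids) < k:
            raise ContractError(
                f"category {cat!r} has {len(ids)} images, fewer than k={k}")
    # stratified random fold assignment
    fold_of: dict[str, int] = {}
    for cat in sorted(by_cat):
        ids = sorted(by_cat[cat])
        perm = rng.permutation(len(ids))
        for pos, idx in enumerate(perm):
            fold_of[ids[idx]] = pos % k
    folds = [sorted(i for i, f in fold_of.items() if f == j) for j in range(k)]

    if stacks is None:
        stacks = compute_stacks(dataset)
    cat_of = {im.id: im.category for im in dataset.images}

    fold_models, fold_aucs, weight_rows = [], [], []
    for j in range(k):
        test_ids = set(folds[j])
        train_ids = [i for i in sorted(fold_of) if i not in test_ids]
        models = {}
        for cat in sorted(by_cat):
            ids = [i for i in train_ids if cat_of[i] == cat]
            samples = _per_image_truth_samples(
                dataset, ids, sigma, n_pos, n_neg, top_frac, bottom_frac, rng)
            ts = assemble_training_set(stacks, samples,
                                       feature_subset=feature_subset)
            seed = int(rng.integers(2**31))
            models[cat] = train_linear_svm(ts, C=C, rng=seed, category=cat)
            weight_rows.append(
                {"fold": j, "category": cat,
                 **dict(zip(models[cat].feature_names, models[cat].weights_))})
        image_aucs = []
        for image_id in sorted(test_ids):
            gaze = dataset.gaze_for(image_id)
            if not gaze:
                continue
            pred = models[cat_of[image_id]].predict_map(stacks[image_id])
            image_aucs.append(auc(pred, gaze_to_pixels(gaze)))
        fold_models.append(models)
        fold_aucs.append(float(np.mean(image_aucs)) if image_aucs else np.nan)

    fold_aucs_arr = np.asarray(fold_aucs, dtype=float)
    return CVResult(
        folds=folds,
        models=fold_models,
        fold_aucs=fold_aucs,
        mean_auc=float(np.nanmean(fold_aucs_arr)),
        std_auc=float(np.nanstd(fold_aucs_arr)),
        weights=pd.DataFrame(weight_rows),
    )


def weight_report(models_across_runs: Sequence[Mapping[str, LinearGazeSaliency]]) -> pd.DataFrame:
    """Per-category mean and population STD of each learned weight
    across runs, plus the descending rank of |Avg| per category.

    ``models_across_runs`` is a sequence of category -> model mappings,
    one per run (cross-validation folds count as runs).
    """
    if len(models_across_runs) < 2:
        raise ContractError("weight_report needs >= 2 runs")
    rows = []
    for run_idx, models in enumerate(models_across_runs):
        for cat, model in models.items():
            rows.append({"run": run_idx, "category": cat,
                         **dict(zip(model.feature_names, model.weights_))})
    df = pd.DataFrame(rows)
    feature_cols = [c for c in df.columns if c not in ("run", "category")]
    out_rows = []
    for cat, grp in df.groupby("category"):
        row = {"category": cat}
        avgs = {}
        for fc in feature_cols:
            row[f"{fc}_avg"] = float(grp[fc].mean())
            row[f"{fc}_std"] = float(np.std(grp[fc]))
            avgs[fc] = abs(row[f"{fc}_avg"])
        ranked = sorted(avgs, key=avgs.get, reverse=True)
        for r, fc in enumerate(ranked, start=1):
            row[f"{fc}_rank"] = r
        out_rows.append(row)
    return pd.DataFrame(out_rows).sort_values("category").reset_index(drop=True)


def save_model(model: LinearGazeSaliency, path: str) -> None:
    """Serialize a fitted model as a flat key=value text file."""
    check_is_fitted(model, "weights_")
    lines = [
        f"category={model.category}",
        f"C={model.C!r}",
        f"tol={model.tol!r}",
        f"random_state={model.random_state}",
        "feature_names=" + ",".join(model.feature_names),
        "weights=" + ",".join(repr(float(w)) for w in model.weights_),
        f"bias={model.bias_!r}",
        "feature_means=" + ",".join(repr(float(v)) for v in model.feature_means_),
        "feature_sds=" + ",".join(repr(float(v)) for v in model.feature_sds_),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path: str) -> LinearGazeSaliency:
    """Load a model written by :func:`save_model`."""
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                key, _, val = line.partition("=")
                kv[key] = val
    model = LinearGazeSaliency(
        C=float(kv["C"]), tol=float(kv["tol"]),
        feature_names=tuple(kv["feature_names"].split(",")),
        category=kv["category"], random_state=int(kv["random_state"]))
    model.weights_ = np.array([float(v) for v in kv["weights"].split(",")])
    model.bias_ = float(kv["bias"])
    model.feature_means_ = np.array([float(v) for v in kv["feature_means"].split(",")])
    model.feature_sds_ = np.array([float(v) for v in kv["feature_sds"].split(",")])
    model.classes_ = np.array([-1, 1])
    model.n_features_in_ = model.weights_.size
    return model
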