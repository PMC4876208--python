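"""Core domain types.

Conventions used throughout the package:

* coordinates are 0-based with ``x`` the column and ``y`` the row;
* bounding boxes are half-open, ``[xmin, xmax) x [ymin, ymax)``;
* all analysis happens on the canonical ``200 x 200`` working frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Side length of the canonical working frame, in pixels.
CANONICAL_SIZE = 200

#: Fixed order of the five per-pixel features.
FEATURE_NAMES = ("color", "intensity", "orientation", "target", "center")


class ContractError(ValueError):
    """A precondition of an operation was violated."""


class FormatError(ValueError):
    """An external file violated its declared format."""


@dataclass
class ImageRecord:
    """An RGB raster stimulus.

    Attributes
    ----------
    id : str
        Unique image identifier.
    pixels : ndarray, shape (H, W, 3)
        Intensities in ``[0, 255]`` (float or uint8).
    category : str
        Search-task category the image belongs to.
    target_present : bool
        Whether the image contains at least one target instance.
    """

    id: str
    pixels: np.ndarray
    category: str = ""
    target_present: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ContractError(
                f"image {self.id!r}: pixels must be HxWx3, got {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ContractError(f"image {self.id!r}: empty raster")
        vals = self.pixels.astype(float)
        if not np.all(np.isfinite(vals)):
            raise ContractError(f"image {self.id!r}: non-finite pixel values")
        if vals.min() < 0 or vals.max() > 255:
            raise ContractError(f"image {self.id!r}: intensities outside [0, 255]")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class GazePoint:
    """One recorded gaze sample, in pixel coordinates of its image."""

    subject: str
    image_id: str
    x: float
    y: float
    t: Optional[float] = None  # milliseconds, if the source recorded time


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned target region, 0-based half-open pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise FormatError(
                f"degenerate box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    @property
    def half_diagonal(self) -> float:
        return float(
            np.hypot((self.xmax - self.xmin) / 2.0, (self.ymax - self.ymin) / 2.0)
        )

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x < self.xmax and self.ymin <= y < self.ymax


@dataclass
class Dataset:
    """A collection of stimuli, gaze samples and target annotations."""

    images: list = field(default_factory=list)
    gaze: list = field(default_factory=list)
    boxes: dict = field(default_factory=dict)  # image_id -> list[BoundingBox]

    def validate(self) -> None:
        ids = {im.id for im in self.images}
        if len(ids) != len(self.images):
            raise ContractError("duplicate image ids in dataset")
        dangling = sorted(
            {g.image_id for g in self.gaze if g.image_id not in ids}
            | {k for k in self.boxes if k not in ids}
        )
        if dangling:
            raise ContractError(f"references to unknown image ids: {dangling[:5]}")

    def image(self, image_id: str) -> ImageRecord:
        for im in self.images:
            if im.id == image_id:
                return im
        raise KeyError(image_id)

    def gaze_for(self, image_id: str, subject: Optional[str] = None) -> list:
        return [
            g
            for g in self.gaze
            if g.image_id == image_id and (subject is None or g.subject == subject)
        ]

    def subjects_on(self, image_id: str) -> list[str]:
        return sorted({g.subject for g in self.gaze if g.image_id == image_id})

    def boxes_for(self, image_id: str) -> list:
        return list(self.boxes.get(image_id, []))


@dataclass
class FeatureMap:
    """A single 200x200 feature channel with values in [0, 1]."""

    values: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (CANONICAL_SIZE, CANONICAL_SIZE):
            raise ContractError(
                f"feature map {self.name!r}: shape {self.values.shape}, "
                f"expected ({CANONICAL_SIZE}, {CANONICAL_SIZE})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ContractError(f"feature map {self.name!r}: non-finite values")
        if self.values.min() < 0.0 or self.values.max() > 1.0 + 1e-12:
            raise ContractError(f"feature map {self.name!r}: values outside [0, 1]")


@dataclass
class FeatureStack:
    """The five feature maps in the fixed order color, intensity,
    orientation, target, center."""

    maps: list

    def __post_init__(self) -> None:
        names = tuple(m.name for m in self.maps)
        if names != FEATURE_NAMES:
            raise ContractError(f"feature stack order {names}, expected {FEATURE_NAMES}")

    def as_array(self) -> np.ndarray:
        """Stack as an (H, W, 5) array in the fixed feature order."""
        return np.stack([m.values for m in self.maps], axis=-1)

    def __getitem__(self, name: str) -> FeatureMap:
        for m in self.maps:
            if m.name == name:
                return m
        raise KeyError(name)
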