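"""Reading and writing external formats.

Images come in as PNG/JPEG, gaze as CSV (``subject,image_id,x,y[,t]``),
target boxes as Pascal-VOC XML (1-based inclusive, converted on read)
or an already 0-based half-open CSV, saliency maps as 8-bit grayscale
PNG or lossless float CSV.  :func:`rescale_to_canonical` maps an image
with its gaze and boxes onto the 200x200 working frame.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from PIL import Image
from skimage.transform import resize

from .datatypes import (
    CANONICAL_SIZE,
    BoundingBox,
    ContractError,
    FormatError,
    GazePoint,
    ImageRecord,
)

__all__ = [
    "read_image",
    "read_fixations",
    "read_voc_boxes",
    "read_boxes_csv",
    "write_saliency_map",
    "read_saliency_map",
    "rescale_to_canonical",
]


def read_image(path: str, *, image_id: Optional[str] = None,
               category: str = "", target_present: bool = False) -> ImageRecord:
    """Load a PNG or JPEG as an :class:`ImageRecord`.

    Grayscale files are expanded to three identical channels.
    """
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    except IOError:
        raise
    except Exception as exc:  # Pillow raises assorted types on corrupt files
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if image_id is None:
        image_id = os.path.splitext(os.path.basename(path))[0]
    return ImageRecord(id=image_id, pixels=arr, category=category,
                       target_present=target_present)


def read_fixations(path: str,
                   images: Optional[Iterable[ImageRecord]] = None) -> list[GazePoint]:
    """Read gaze samples from a CSV with header ``subject,image_id,x,y[,t]``.

    If ``images`` is given, every coordinate is validated against the
    referenced image's half-open bounds; offending rows raise (no silent
    clamping).
    """
    if not os.path.exists(path):
        raise IOError(f"gaze file not found: {path}")
    df = pd.read_csv(path, dtype={"subject": str, "image_id": str})
    required = {"subject", "image_id", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: gaze CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    points = [
        GazePoint(
            subject=row.subject,
            image_id=row.image_id,
            x=float(row.x),
            y=float(row.y),
            t=float(row.t) if "t" in df.columns and pd.notna(getattr(row, "t", None)) else None,
        )
        for row in df.itertuples(index=False)
    ]
    if images is not None:
        dims = {im.id: (im.width, im.height) for im in images}
        bad = []
        for i, g in enumerate(points):
            if g.image_id in dims:
                w, h = dims[g.image_id]
                if not (0 <= g.x < w and 0 <= g.y < h):
                    bad.append(i + 2)  # 1-based file line incl. header
        if bad:
            raise ContractError(
                f"{path}: gaze coordinates outside image bounds on rows {bad}"
            )
    return points


def read_voc_boxes(path: str) -> list[BoundingBox]:
    """Parse a Pascal-VOC-style annotation XML.

    VOC ``bndbox`` coordinates are 1-based inclusive; they are converted
    to the package's 0-based half-open convention
    (``xmin' = xmin - 1``, ``xmax' = xmax``, same for ``y``).
    """
    if not os.path.exists(path):
        raise IOError(f"annotation file not found: {path}")
    tree = etree.parse(path)
    boxes = []
    for obj in tree.findall(".//object"):
        name_el = obj.find("name")
        label = name_el.text.strip() if name_el is not None and name_el.text else ""
        bb = obj.find("bndbox")
        if bb is None:
            raise FormatError(f"{path}: <object> without <bndbox>")
        coords = {}
        for tag in ("xmin", "ymin", "xmax", "ymax"):
            el = bb.find(tag)
            if el is None or el.text is None:
                raise FormatError(f"{path}: <bndbox> missing <{tag}>")
            coords[tag] = float(el.text)
        try:
            boxes.append(
                BoundingBox(
                    xmin=coords["xmin"] - 1,
                    ymin=coords["ymin"] - 1,
                    xmax=coords["xmax"],
                    ymax=coords["ymax"],
                    label=label,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return boxes


def read_boxes_csv(path: str) -> dict[str, list[BoundingBox]]:
    """Read boxes from CSV ``image_id,label,xmin,ymin,xmax,ymax``
    (already 0-based half-open).  Returns a map image_id -> boxes."""
    if not os.path.exists(path):
        raise IOError(f"box file not found: {path}")
    df = pd.read_csv(path, dtype={"image_id": str, "label": str})
    out: dict[str, list[BoundingBox]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.image_id, []).append(
            BoundingBox(xmin=float(row.xmin), ymin=float(row.ymin),
                        xmax=float(row.xmax), ymax=float(row.ymax),
                        label=str(row.label))
        )
    return out


def write_saliency_map(values: np.ndarray, path: str, mode: str = "png8") -> None:
    """Write a saliency map with values in [0, 1].

    ``png8`` quantises to 8-bit grayscale (round-half-away-from-zero, so
    round-trip error is at most 1/255 per pixel); ``float_csv`` is a
    lossless full-precision CSV.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ContractError("saliency map contains non-finite values")
    if values.min() < 0.0 or values.max() > 1.0:
        raise ContractError(
            f"saliency map values outside [0, 1]: range "
            f"[{values.min():.4g}, {values.max():.4g}]"
        )
    if mode == "png8":
        # np.floor(x + 0.5) is round-half-away-from-zero for x >= 0
        q = np.floor(values * 255.0 + 0.5).astype(np.uint8)
        Image.fromarray(q, mode="L").save(path, format="PNG")
    elif mode == "float_csv":
        pd.DataFrame(values).to_csv(path, header=False, index=False,
                                    float_format="%.17g")
    else:
        raise ContractError(f"unknown saliency map mode {mode!r}")


def read_saliency_map(path: str, mode: str = "png8") -> np.ndarray:
    """Read a saliency map written by :func:`write_saliency_map`."""
    if not os.path.exists(path):
        raise IOError(f"saliency map not found: {path}")
    if mode == "png8":
        with Image.open(path) as im:
            return np.asarray(im.convert("L"), dtype=float) / 255.0
    if mode == "float_csv":
        return pd.read_csv(path, header=None,
                           float_precision="round_trip").to_numpy(dtype=float)
    raise ContractError(f"unknown saliency map mode {mode!r}")


def rescale_to_canonical(
    image: ImageRecord,
    gaze: Sequence[GazePoint] = (),
    boxes: Sequence[BoundingBox] = (),
) -> tuple[ImageRecord, list[GazePoint], list[BoundingBox]]:
    """Resample an image (bilinear) plus its gaze and boxes to 200x200.

    Gaze coordinates are multiplied by ``(200/width, 200/height)`` and
    floored to pixel indices; box corners are scaled the same way, and a
    box that would collapse is expanded to at least 1x1.
    """
    sx = CANONICAL_SIZE / image.width
    sy = CANONICAL_SIZE / image.height
    if image.width == CANONICAL_SIZE and image.height == CANONICAL_SIZE:
        pix = image.pixels.astype(float)
    else:
        pix = resize(image.pixels.astype(float), (CANONICAL_SIZE, CANONICAL_SIZE),
                     order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    scaled_img = ImageRecord(id=image.id, pixels=pix, category=image.category,
                             target_present=image.target_present)
    scaled_gaze = [
        GazePoint(
            subject=g.subject, image_id=g.image_id,
            x=min(float(np.floor(g.x * sx)), CANONICAL_SIZE - 1),
            y=min(float(np.floor(g.y * sy)), CANONICAL_SIZE - 1),
            t=g.t,
        )
        for g in gaze
    ]
    scaled_boxes = []
    for b in boxes:
        xmin, xmax = b.xmin * sx, b.xmax * sx
        ymin, ymax = b.ymin * sy, b.ymax * sy
        if xmax - xmin < 1.0:
            xmax = min(xmin + 1.0, CANONICAL_SIZE)
            xmin = xmax - 1.0
        if ymax - ymin < 1.0:
            ymax = min(ymin + 1.0, CANONICAL_SIZE)
            ymin = ymax - 1.0
        scaled_boxes.append(
            BoundingBox(xmin=xmin, ymin=ymin, xmax=xmax, ymax=ymax, label=b.label)
        )
    return scaled_img, scaled_gaze, scaled_boxes
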