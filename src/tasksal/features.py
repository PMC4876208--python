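"""Per-pixel feature maps on the canonical 200x200 frame.

Five channels in fixed order:

``color``, ``intensity``, ``orientation``
    Bottom-up conspicuity in the style of the classic center-surround
    saliency architecture: a Gaussian pyramid of the image, across-scale
    differences between fine ("center") and coarse ("surround") levels,
    a max-promoting normalization of each intermediate map, and
    summation into one channel.  Depths are scaled down for the 200x200
    working frame (center levels {2, 3}, surround offsets {2, 3} on a
    level-0..6 pyramid).

``target``
    Inside each annotated target box, the distance of the pixel to the
    box center normalized by the box half-diagonal (0 at the center,
    ~1 at the corners); 0 outside every box.  Overlaps take the minimum
    normalized distance.  An inverted encoding (peak at the box center)
    is available via ``invert=True``.

``center``
    Distance of each pixel to the frame center normalized by the frame
    half-diagonal, the standard centre-bias prior.

Every channel is individually max-normalized to [0, 1]; an all-constant
input yields an all-zero conspicuity channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve, maximum_filter
from skimage.filters import gabor_kernel
from skimage.transform import pyramid_gaussian, resize

from .datatypes import (
    CANONICAL_SIZE,
    FEATURE_NAMES,
    BoundingBox,
    ContractError,
    FeatureMap,
    FeatureStack,
    ImageRecord,
)

__all__ = [
    "FEATURE_NAMES",
    "ConspicuityConfig",
    "conspicuity_channels",
    "target_feature_map",
    "center_bias_map",
    "build_feature_stack",
]


@dataclass(frozen=True)
class ConspicuityConfig:
    """Tunables of the bottom-up conspicuity channels.

    ``max_level`` is the deepest pyramid level (level k has side
    ~200/2^k); center/surround pairs are (c, c+d) for c in
    ``center_levels`` and d in ``deltas``.  ``gabor_wavelength`` is in
    pixels at the respective pyramid level.
    """

    max_level: int = 6
    center_levels: tuple[int, ...] = (2, 3)
    deltas: tuple[int, ...] = (2, 3)
    gabor_wavelength: float = 7.0
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    local_max_size: int = 3

    def pairs(self) -> list[tuple[int, int]]:
        return [
            (c, c + d)
            for c in self.center_levels
            for d in self.deltas
            if c + d <= self.max_level
        ]


DEFAULT_CONSPICUITY = ConspicuityConfig()


def _gaussian_pyramid(channel: np.ndarray, max_level: int) -> list[np.ndarray]:
    return list(
        pyramid_gaussian(channel, max_layer=max_level, downscale=2,
                         preserve_range=True, channel_axis=None)
    )


def _center_surround(pyr: Sequence[np.ndarray], c: int, s: int) -> np.ndarray:
    """|center - surround| with the surround upsampled to the center scale."""
    surround = resize(pyr[s], pyr[c].shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return np.abs(pyr[c] - surround)


def _normalize_peaks(m: np.ndarray, local_size: int) -> np.ndarray:
    """Max-promoting normalization.

    The map is scaled to [0, 1]; with M its global maximum (1 after
    scaling) and m-bar the mean of its other local maxima, the map is
    multiplied by (M - m-bar)^2.  Maps with one dominant peak keep their
    weight; maps with many comparable peaks are suppressed.
    """
    top = m.max()
    if top <= 0:
        return np.zeros_like(m)
    m = m / top
    footprint = np.ones((local_size, local_size), dtype=bool)
    is_peak = (m == maximum_filter(m, footprint=footprint, mode="nearest"))
    peaks = m[is_peak]
    others = peaks[peaks < 1.0 - 1e-12]
    m_bar = float(others.mean()) if others.size else 0.0
    return m * (1.0 - m_bar) ** 2


def _sum_across_scales(maps: list[np.ndarray], cfg: ConspicuityConfig) -> np.ndarray:
    out = np.zeros((CANONICAL_SIZE, CANONICAL_SIZE))
    for m in maps:
        n = _normalize_peaks(m, cfg.local_max_size)
        out += resize(n, out.shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return out


def _max_normalize(values: np.ndarray) -> np.ndarray:
    top = values.max()
    if top <= 1e-12:
        return np.zeros_like(values)
    return np.clip(values / top, 0.0, 1.0)


@lru_cache(maxsize=8)
def _gabor_bank(wavelength: float, orientations: tuple[float, ...]):
    """Zero-DC Gabor kernels (real and imaginary parts) per orientation.

    The real (even) part has its mean removed so a constant input gives
    exactly zero response, making the orientation channel invariant to
    global intensity shifts.
    """
    bank = []
    for theta_deg in orientations:
        k = gabor_kernel(frequency=1.0 / wavelength,
                         theta=np.deg2rad(theta_deg))
        kr = np.real(k)
        kr = kr - kr.mean()
        ki = np.imag(k)
        bank.append((kr, ki))
    return bank


def _gabor_energy(level_img: np.ndarray, kr: np.ndarray, ki: np.ndarray) -> np.ndarray:
    if min(level_img.shape) < 3:
        return np.zeros_like(level_img)
    re = convolve(level_img, kr, mode="nearest")
    im = convolve(level_img, ki, mode="nearest")
    return np.hypot(re, im)


def conspicuity_channels(
    image: ImageRecord, config: ConspicuityConfig = DEFAULT_CONSPICUITY
) -> tuple[FeatureMap, FeatureMap, FeatureMap]:
    """Compute the color, intensity and orientation conspicuity maps.

    The input must already be on the canonical 200x200 frame.
    """
    if image.height != CANONICAL_SIZE or image.width != CANONICAL_SIZE:
        raise ContractError(
            f"conspicuity_channels requires a {CANONICAL_SIZE}x{CANONICAL_SIZE} "
            f"image, got {image.height}x{image.width}"
        )
    pix = image.pixels.astype(float)
    r, g, b = pix[..., 0], pix[..., 1], pix[..., 2]
    intensity = (r + g + b) / 3.0
    # Linear opponent channels: zero for achromatic input, and linear in
    # the pixel values so center-surround differences cancel global shifts.
    rg = r - g
    by = b - (r + g) / 2.0

    pyr_i = _gaussian_pyramid(intensity, config.max_level)
    pyr_rg = _gaussian_pyramid(rg, config.max_level)
    pyr_by = _gaussian_pyramid(by, config.max_level)

    pairs = config.pairs()
    int_maps = [_center_surround(pyr_i, c, s) for c, s in pairs]
    col_maps = [_center_surround(pyr_rg, c, s) for c, s in pairs]
    col_maps += [_center_surround(pyr_by, c, s) for c, s in pairs]

    bank = _gabor_bank(config.gabor_wavelength, tuple(config.orientations))
    levels_needed = sorted({lv for pair in pairs for lv in pair})
    ori_maps = []
    for kr, ki in bank:
        responses = {lv: _gabor_energy(pyr_i[lv], kr, ki) for lv in levels_needed}
        pyr_o = [responses.get(lv, np.zeros((1, 1)))
                 for lv in range(config.max_level + 1)]
        ori_maps += [_center_surround(pyr_o, c, s) for c, s in pairs]

    color = _max_normalize(_sum_across_scales(col_maps, config))
    inten = _max_normalize(_sum_across_scales(int_maps, config))
    orient = _max_normalize(_sum_across_scales(ori_maps, config))
    return (
        FeatureMap(values=color, name="color"),
        FeatureMap(values=inten, name="intensity"),
        FeatureMap(values=orient, name="orientation"),
    )


def target_feature_map(boxes: Sequence[BoundingBox], invert: bool = False) -> FeatureMap:
    """Distance-to-target-center feature.

    For a pixel covered by one or more boxes, the Euclidean distance from
    the pixel center to the covering box's center divided by that box's
    half-diagonal (the minimum over covering boxes); 0 outside all boxes.
    With ``invert=True`` the inside-box values become ``1 - distance``
    (peak at the box center), still 0 outside.
    """
    n = CANONICAL_SIZE
    for b in boxes:
        if b.xmin < 0 or b.ymin < 0 or b.xmax > n or b.ymax > n:
            raise ContractError(f"box {b} outside the canonical frame")
    xs = np.arange(n) + 0.5
    ys = np.arange(n) + 0.5
    xx, yy = np.meshgrid(xs, ys)
    values = np.zeros((n, n))
    covered = np.zeros((n, n), dtype=bool)
    for b in boxes:
        cx, cy = b.center
        mask = (xx >= b.xmin) & (xx < b.xmax) & (yy >= b.ymin) & (yy < b.ymax)
        dist = np.hypot(xx - cx, yy - cy) / b.half_diagonal
        dist = np.clip(dist, 0.0, 1.0)
        update = mask & (~covered | (dist < values))
        values[update] = dist[update]
        covered |= mask
    if invert:
        values[covered] = 1.0 - values[covered]
    values[~covered] = 0.0
    return FeatureMap(values=values, name="target")


@lru_cache(maxsize=1)
def _center_bias_values() -> np.ndarray:
    n = CANONICAL_SIZE
    coords = np.arange(n, dtype=float)
    cx = cy = (n - 1) / 2.0  # (99.5, 99.5)
    xx, yy = np.meshgrid(coords, coords)
    half_diag = np.hypot(n / 2.0, n / 2.0)
    vals = np.hypot(xx - cx, yy - cy) / half_diag
    vals.setflags(write=False)
    return vals


def center_bias_map() -> FeatureMap:
    """Normalized distance-to-frame-center prior (0 at center, ~1 at corners)."""
    return FeatureMap(values=_center_bias_values().copy(), name="center")


def build_feature_stack(
    image: ImageRecord,
    boxes: Sequence[BoundingBox] = (),
    config: ConspicuityConfig = DEFAULT_CONSPICUITY,
    invert_target: bool = False,
) -> FeatureStack:
    """All five feature maps for one canonical image, fixed order,
    each individually max-normalized to [0, 1]."""
    color, inten, orient = conspicuity_channels(image, config)
    target = target_feature_map(boxes, invert=invert_target)
    center = center_bias_map()
    return FeatureStack(maps=[color, inten, orient, target, center])
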