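"""Distance-transform dissimilarity between binary clutch silhouettes.

Two binary masks of the same nest (before/after manipulation) are compared
by (1) registering them — translation so foreground centroids coincide and
an isotropic rescale so foreground areas match, absorbing small framing
differences between the photographs — and (2) counting, with a pixel
tolerance, how much foreground of either image has no counterpart in the
other.  A pixel of one mask is *matched* when the Euclidean distance
transform of the other mask at that pixel is at most ``tolerance_px``.  The
score is

    dissimilarity = (# unmatched pixels of both masks) / (# pixels in union)

so 0 means identical silhouettes and 1 means the shapes are everywhere
farther apart than the tolerance.  The denominator is the union of the
registered foregrounds, making the score independent of frame size.

:func:`dissimilarity` registers both masks into a *common* canonical frame
(each centroid moved to the canvas center, each area scaled to the
geometric mean of the two areas), which makes the score exactly symmetric
in its arguments.  :func:`register` exposes the one-sided variant (moving
mask onto a fixed reference).

Rotation is deliberately not searched for: overhead nest-cup photographs
share an orientation, and rotating one mask onto the other would cancel the
very arrangement change the score is meant to capture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, InvalidInputError, InvalidParameterError

__all__ = [
    "ClutchMask",
    "DissimilarityScore",
    "register",
    "dissimilarity",
    "load_mask",
    "save_mask",
]

_MAX_FOREGROUND_FRACTION = 0.9


@dataclass
class ClutchMask:
    """A binary clutch silhouette (True = egg pixels)."""

    pixels: np.ndarray
    nest_id: str | None = None
    phase: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InvalidInputError(f"mask must be 2-D, got shape {px.shape}")
        px = px.astype(bool)
        if not px.any():
            raise EmptyMaskError("mask has no foreground pixels")
        if px.mean() >= _MAX_FOREGROUND_FRACTION:
            raise InvalidInputError("mask foreground covers >= 90% of the frame")
        self.pixels = px

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid of the foreground."""
        rows, cols = np.nonzero(self.pixels)
        return float(rows.mean()), float(cols.mean())


@dataclass(frozen=True)
class DissimilarityScore:
    """Proportion of mismatched foreground, in [0, 1]."""

    value: float
    tolerance_px: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise InvalidInputError(f"dissimilarity {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


def _resample(
    pixels: np.ndarray,
    scale: float,
    c_in: tuple[float, float],
    c_out: tuple[float, float],
    shape: tuple[int, int],
) -> np.ndarray:
    """Nearest-neighbour similarity resample: output point y maps to input
    point c_in + (y - c_out) / scale."""
    matrix = np.diag([1.0 / scale, 1.0 / scale])
    offset = np.asarray(c_in) - np.asarray(c_out) / scale
    out = ndimage.affine_transform(
        pixels.astype(np.float32), matrix, offset=offset, output_shape=shape,
        order=0, mode="constant", cval=0.0,
    )
    return out > 0.5


def register(reference: ClutchMask, moving: ClutchMask) -> ClutchMask:
    """Translate/scale ``moving`` so its centroid and area match ``reference``.

    The output frame is the elementwise-max of the two frames, enlarged if
    the rescaled moving foreground would extend past its bottom/right edge.
    Content that would cross the frame origin (possible only when the two
    areas differ far more than one egg's worth) is clipped; comparable
    before/after clutch masks are unaffected.  :func:`dissimilarity` uses a
    clipping-free symmetric canvas instead of this one-sided registration.
    """
    scale = math.sqrt(reference.area / moving.area)
    c_in = moving.centroid
    c_out = reference.centroid

    rows, cols = np.nonzero(moving.pixels)
    need_r = int(math.ceil(np.max(np.abs(rows - c_in[0])) * scale + c_out[0])) + 2
    need_c = int(math.ceil(np.max(np.abs(cols - c_in[1])) * scale + c_out[1])) + 2
    shape = (
        max(reference.pixels.shape[0], moving.pixels.shape[0], need_r),
        max(reference.pixels.shape[1], moving.pixels.shape[1], need_c),
    )
    out = _resample(moving.pixels, scale, c_in, c_out, shape)
    return ClutchMask(out, nest_id=moving.nest_id, phase=moving.phase)


def _canonical_pair(a: ClutchMask, b: ClutchMask) -> tuple[np.ndarray, np.ndarray]:
    """Register both masks into one shared frame: centroids at the canvas
    center, both areas scaled to the geometric mean of the two areas.  The
    construction is symmetric in (a, b)."""
    target_area = math.sqrt(a.area * b.area)
    scales = [math.sqrt(target_area / m.area) for m in (a, b)]
    half = 0.0
    for m, s in zip((a, b), scales):
        rows, cols = np.nonzero(m.pixels)
        cr, cc = m.centroid
        ext = max(np.max(np.abs(rows - cr)), np.max(np.abs(cols - cc)))
        half = max(half, ext * s)
    side = int(math.ceil(2 * half)) + 5
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    return tuple(
        _resample(m.pixels, s, m.centroid, center, (side, side))
        for m, s in zip((a, b), scales)
    )


def dissimilarity(
    before: ClutchMask, after: ClutchMask, tolerance_px: float = 2.0
) -> DissimilarityScore:
    """Proportion of mismatch between two registered clutch masks.

    ``tolerance_px`` (>= 0) is the distance within which foreground of one
    image still counts as matched by the other; it absorbs resampling and
    annotation error.  The score is symmetric, 0 for identical masks, and
    monotone non-increasing in the tolerance.
    """
    if not (tolerance_px >= 0.0):
        raise InvalidParameterError(f"tolerance_px must be >= 0, got {tolerance_px}")
    am, bm = _canonical_pair(before, after)
    union = int((am | bm).sum())
    if math.isinf(tolerance_px):
        return DissimilarityScore(0.0, tolerance_px)
    dt_a = ndimage.distance_transform_edt(~am)
    dt_b = ndimage.distance_transform_edt(~bm)
    unmatched = int((am & (dt_b > tolerance_px)).sum()) + int((bm & (dt_a > tolerance_px)).sum())
    return DissimilarityScore(unmatched / union, tolerance_px)


def load_mask(
    path, nest_id: str | None = None, phase: str | None = None, threshold: float | None = None
) -> ClutchMask:
    """Read a PNG mask (0 = background, 255 = foreground).

    Color images are averaged to grayscale.  Non-binary grayscale input is
    thresholded at ``threshold`` if given, else by Otsu's method.
    """
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    img = img.astype(float)
    values = np.unique(img)
    if threshold is not None:
        binary = img > threshold
    elif values.size <= 2:
        binary = img > img.min()
    else:
        from skimage.filters import threshold_otsu

        binary = img > threshold_otsu(img)
    return ClutchMask(binary, nest_id=nest_id, phase=phase)


def save_mask(mask: ClutchMask, path) -> None:
    """Write a mask as an 8-bit PNG (0/255)."""
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
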