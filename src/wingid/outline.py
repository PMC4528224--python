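"""Raster image -> single closed binary outline.

The processing chain mirrors how silhouette photographs of wings (dark object
on a near-white background) are reduced to an outline: grayscale conversion,
automatic (Otsu) binarization with polarity detection, speckle removal, one
morphological opening, interior hole filling, and Moore-neighbour boundary
tracing of the single remaining component.

Pixel convention here is image-style ``(row, col)`` with row 0 at the top;
conversion to mathematical y-up coordinates happens once, inside
:mod:`wingid.chaincode`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ImageError, NoObjectError, OutlineError

logger = logging.getLogger(__name__)

# ITU-R 601 luminance weights used for the 8-bit grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])
_SELEM = np.ones((3, 3), dtype=bool)  # structuring element for the opening
#: speckle components smaller than this fraction of the image area are noise
DEFAULT_MIN_AREA_FRAC = 1e-3


@dataclass(frozen=True)
class BinaryOutline:
    """Closed 8-connected single-pixel outline of one filled region.

    ``pixels`` is the ordered ``(row, col)`` traversal produced by boundary
    tracing (each pixel exactly once, consecutive pixels 8-neighbours, last
    adjacent to first); ``foreground_area_px`` is the filled region's area.
    """

    pixels: np.ndarray
    image_shape: tuple
    foreground_area_px: int

    def __len__(self) -> int:
        return len(self.pixels)


def read_image(path) -> np.ndarray:
    """Read a BMP/JPEG/PNG image into a numpy array (grayscale, RGB or RGBA)."""
    try:
        with Image.open(path) as im:
            return np.asarray(im)
    except (OSError, ValueError) as exc:
        raise ImageError(f"cannot read image {path}: {exc}") from exc


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 1-, 3- or 4-channel raster to 8-bit grayscale (ITU-R 601).

    Four-channel (RGBA) input is alpha-composited onto a white background
    first, matching the photographic convention of a dark wing on white.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ImageError("empty image")
    if img.ndim == 2:
        if img.dtype == np.uint8:
            return img
        arr = img.astype(float)
        if arr.max() <= 1.0:
            arr = arr * 255.0
        return np.clip(np.round(arr), 0, 255).astype(np.uint8)
    if img.ndim != 3 or img.shape[2] not in (3, 4):
        raise ImageError(f"unsupported image layout with shape {img.shape}")
    arr = img.astype(float)
    if img.dtype != np.uint8 and arr.max() <= 1.0:
        arr = arr * 255.0
    if arr.shape[2] == 4:
        alpha = arr[:, :, 3:4] / 255.0
        arr = arr[:, :, :3] * alpha + 255.0 * (1.0 - alpha)
    gray = arr[:, :, :3] @ _LUMA
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def binarize(gray: np.ndarray) -> np.ndarray:
    """Otsu-threshold a grayscale image; foreground = the object, either polarity.

    The object class is detected as the Otsu class in the minority along the
    image border frame (the background surrounds the object), so a white
    object on black binarizes identically to a dark object on white.

    Raises
    ------
    NoObjectError
        For a uniform image (no bimodality, nothing to segment) or when the
        detected foreground is empty.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2 or gray.size == 0:
        raise ImageError("binarize expects a non-empty 2-D grayscale image")
    if np.ptp(gray) == 0:
        raise NoObjectError("no object found: uniform image")
    th = threshold_otsu(gray)
    dark = gray <= th
    border = np.concatenate([dark[0, :], dark[-1, :], dark[:, 0], dark[:, -1]])
    foreground = dark if border.mean() < 0.5 else ~dark
    if not foreground.any():
        raise NoObjectError("no object found after thresholding")
    return foreground


def clean_and_fill(
    binary: np.ndarray,
    min_area_frac: float = DEFAULT_MIN_AREA_FRAC,
    selem: np.ndarray = _SELEM,
) -> np.ndarray:
    """Noise reduction, one opening (erosion + dilation), hole filling.

    Speckles below ``min_area_frac`` of the image area are removed, a single
    3x3 opening smooths the boundary, interior holes are filled, and only the
    largest connected component is kept (ties broken by scan order, with a
    warning).  Applying this twice equals applying it once.
    """
    mask = np.asarray(binary, dtype=bool)
    min_area = max(1, int(round(min_area_frac * mask.size)))
    cleaned = _remove_speckles(mask, min_area)
    se = _as_selem(selem)
    opened = ndimage.binary_dilation(ndimage.binary_erosion(cleaned, se), se)
    filled = ndimage.binary_fill_holes(opened)
    labels, n = ndimage.label(filled, structure=np.ones((3, 3)))
    if n == 0:
        raise NoObjectError("no component above the speckle area threshold survived cleaning")
    areas = ndimage.sum_labels(filled, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas))  # first maximum in label (scan) order
    if n > 1:
        if np.sum(areas == areas[best]) > 1:
            logger.warning("largest-component tie (%d px); keeping the first in scan order", int(areas[best]))
        else:
            logger.warning("multiple components after cleaning; keeping the largest (%d of %d px total)",
                           int(areas[best]), int(areas.sum()))
    return labels == best + 1


def _remove_speckles(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with area below ``min_area`` pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    return np.isin(labels, keep)


def _as_selem(selem) -> np.ndarray:
    s = np.asarray(selem, dtype=bool)
    if s.ndim != 2:
        raise ImageError("structuring element must be 2-D")
    return s


def extract_outline(binary: np.ndarray) -> BinaryOutline:
    """Trace the closed border of a single hole-free component.

    Raises
    ------
    OutlineError
        If there is not exactly one component, the component touches the
        image border (the outline would be clipped), interior holes remain,
        or the traced outline is shorter than 8 pixels.
    """
    mask = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        raise OutlineError("empty binary image: nothing to outline")
    if n > 1:
        raise OutlineError(f"expected a single component, found {n}; run clean_and_fill first")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise OutlineError("component touches the image border; the outline would be clipped")
    if not np.array_equal(ndimage.binary_fill_holes(mask), mask):
        raise OutlineError("component has interior holes; run clean_and_fill first")

    start = np.unravel_index(int(np.argmax(mask)), mask.shape)  # first fg pixel in scan order
    path = _moore_trace(mask, start)
    if len(path) < 8:
        raise OutlineError(f"outline of {len(path)} px is below the 8 px minimum")
    pixels = np.asarray(path, dtype=np.int64)
    uniq = {tuple(p) for p in path}
    if len(uniq) != len(path):
        raise OutlineError("boundary trace revisited a pixel (1-px-wide structure?)")
    return BinaryOutline(pixels=pixels, image_shape=mask.shape, foreground_area_px=int(mask.sum()))


# clockwise Moore neighbourhood in (row, col), starting west
_RING = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_RING_INDEX = {d: i for i, d in enumerate(_RING)}


def _moore_trace(mask: np.ndarray, start: tuple) -> list:
    """Moore-neighbour boundary tracing with Jacob's stopping criterion.

    ``start`` must be the first foreground pixel in raster-scan order so the
    initial backtrack pixel (its west neighbour) is guaranteed background.
    Returns the ordered boundary pixels; a single isolated pixel returns a
    length-1 path.
    """
    h, w = mask.shape

    def step(cur, back):
        i = _RING_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        for k in range(1, 9):
            dr, dc = _RING[(i + k) % 8]
            r, c = cur[0] + dr, cur[1] + dc
            if 0 <= r < h and 0 <= c < w and mask[r, c]:
                pr, pc = _RING[(i + k - 1) % 8]
                return (r, c), (cur[0] + pr, cur[1] + pc)
        return None

    back0 = (start[0], start[1] - 1)
    state = (start, back0)
    path = [start]
    nxt = step(*state)
    if nxt is None:
        return path  # isolated single pixel
    limit = 4 * mask.size
    while nxt != (start, back0):
        path.append(nxt[0])
        state = nxt
        nxt = step(*state)
        if len(path) > limit:
            raise OutlineError("boundary tracing failed to close")
    return path
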