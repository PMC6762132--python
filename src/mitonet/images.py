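"""Micrograph preprocessing: raw image -> labeled one-pixel skeleton.

Steps mirror the standard fluorescence-micrograph workflow for
mitochondrial networks: mask out legends/artifact regions, isolate the
mitochondrial channel, convert to grayscale, binarize at a global Otsu
threshold, thin to a one-pixel-wide topology-preserving skeleton, and
label its 8-connected components.  Intensities are normalized to [0, 1]
on load regardless of bit depth so one threshold convention serves 8-
and 16-bit inputs alike.
"""

from __future__ import annotations

import json

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize as sk_skeletonize

__all__ = [
    "load_image",
    "preprocess",
    "to_grayscale",
    "otsu_threshold",
    "binarize",
    "skeletonize_mask",
    "label_components",
    "extract_skeleton",
    "load_exclusion_regions",
]

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def load_image(path) -> np.ndarray:
    """Read a TIFF/PNG micrograph as float in [0, 1] (channels preserved)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    arr = arr.astype(float)
    if arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
    return arr


def _as_float(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    return arr


def load_exclusion_regions(path) -> list:
    """Read exclusion regions from a JSON file.

    The file holds a list of rectangles ``{"row": r, "col": c,
    "height": h, "width": w}`` or polygons ``{"rows": [...], "cols":
    [...]}`` in 0-based, row-major pixel coordinates.
    """
    with open(path) as fh:
        return json.load(fh)


def _region_mask(shape, regions) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for reg in regions:
        if "rows" in reg:
            rr, cc = draw_polygon(reg["rows"], reg["cols"], shape=shape)
            mask[rr, cc] = True
        else:
            r, c = reg["row"], reg["col"]
            h, w = reg["height"], reg["width"]
            if r < 0 or c < 0 or r + h > shape[0] or c + w > shape[1]:
                raise ValueError(f"exclusion region {reg} outside image bounds")
            mask[r:r + h, c:c + w] = True
    return mask


def preprocess(image, exclusion_regions=None, channel=None) -> np.ndarray:
    """Remove legends/artifacts and isolate the mitochondrial channel.

    ``exclusion_regions`` (rectangles/polygons, see
    :func:`load_exclusion_regions`) are set to background.  ``channel``
    selects the channel carrying the mitochondrial stain: ``"red"``,
    ``"green"``, ``"blue"``, an integer index, or ``None`` for a
    luminance conversion of multichannel input.  Returns a
    single-channel image.
    """
    arr = _as_float(image)
    if channel is not None and arr.ndim == 2:
        raise ValueError("channel selection requested on a single-channel image")
    if arr.ndim == 3:
        idx = _CHANNEL_INDEX.get(channel, channel)
        if idx is not None:
            if not 0 <= idx < arr.shape[2]:
                raise ValueError(f"channel {channel!r} absent from image")
            arr = arr[:, :, idx]
        else:
            arr = to_grayscale(arr)
    if exclusion_regions:
        arr = arr.copy()
        arr[_region_mask(arr.shape, exclusion_regions)] = 0.0
    return arr


def to_grayscale(image) -> np.ndarray:
    """Collapse 1-4 channels to one by luminance-weighted averaging.

    Monotone in every input channel, and constant images map to the same
    constant.  Alpha channels are ignored.
    """
    arr = _as_float(image)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or not 1 <= arr.shape[2] <= 4:
        raise ValueError("expected a 2-D image with 1-4 channels")
    if arr.shape[2] == 1:
        return arr[:, :, 0]
    rgb = arr[:, :, :3]
    if rgb.shape[2] == 2:
        return rgb.mean(axis=2)
    w = np.array([0.2125, 0.7154, 0.0721])  # ITU-R 709 luminance
    return rgb @ w


def otsu_threshold(image) -> float:
    """Global threshold minimizing intra-class intensity variance over a
    256-bin histogram."""
    arr = _as_float(image)
    if np.unique(arr).size < 2:
        raise ValueError("degenerate histogram: image has a single intensity")
    return float(threshold_otsu(arr, nbins=256))


def binarize(image, level: float) -> np.ndarray:
    """Foreground mask: pixels strictly brighter than ``level``."""
    return _as_float(image) > level


def skeletonize_mask(mask) -> np.ndarray:
    """Thin a binary mask to a one-pixel-wide, 8-connected skeleton.

    The thinning is topology preserving: component count and each
    component's cycle rank survive, and re-thinning a skeleton leaves it
    unchanged.
    """
    return sk_skeletonize(np.asarray(mask, dtype=bool))


def label_components(skeleton) -> np.ndarray:
    """Label 8-connected skeleton components 1..C (0 = background)."""
    return sk_label(np.asarray(skeleton, dtype=bool), connectivity=2)


def extract_skeleton(image, exclusion_regions=None, channel=None,
                     level: float = None) -> tuple:
    """Full pipeline: micrograph -> (skeleton mask, labels).

    ``level`` overrides the automatic Otsu threshold when a manual
    intensity cut is preferred.
    """
    gray = preprocess(image, exclusion_regions=exclusion_regions, channel=channel)
    gray = to_grayscale(gray)
    if level is None:
        level = otsu_threshold(gray)
    skel = skeletonize_mask(binarize(gray, level))
    return skel, label_components(skel)
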