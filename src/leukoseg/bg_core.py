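"""Core B-G channel-difference segmentation primitives.

The segmentation statistic is the per-pixel difference between the blue and
green channels of an 8-bit RGB micrograph, saturated at zero.  In
Wright-Giemsa stained smears the dyed nuclei (and platelets) carry a large
B-G value while erythrocytes, background, pale cytoplasm and dye precipitate
do not, so a fixed empirical threshold separates nuclear material without any
per-image threshold search.  Platelets are then removed by size filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: Empirical threshold band within which the fixed threshold is considered
#: compliant with the statistic's separability guarantees (stain-like debris
#: stays below 50, nucleus interiors above 110).
T0_BAND = (50, 100)

#: Default fixed threshold: midpoint of the compliant band.
DEFAULT_T0 = 80

#: Default minimum connected-component area (pixels) for a nucleus lobe at a
#: nominal 1024x768 capture.  Platelets are far smaller, lobes far larger;
#: this value is scale-dependent and configurable.
DEFAULT_MIN_NUCLEUS_AREA = 500


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters for thresholding and size filtering.

    Attributes
    ----------
    t0 : int
        Fixed binarization threshold applied to the B-G difference map
        (inclusive: a pixel is foreground iff ``diff >= t0``).
    min_nucleus_area_px : int
        Connected components smaller than this many pixels are discarded
        (platelet removal).  The boundary is inclusive: a component of
        exactly this area survives.
    connectivity : int
        4 or 8; pixel connectivity used for component labeling.
    """

    t0: int = DEFAULT_T0
    min_nucleus_area_px: int = DEFAULT_MIN_NUCLEUS_AREA
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.t0 <= 255:
            raise ValueError(f"t0 must be in [0, 255], got {self.t0}")
        if not T0_BAND[0] <= self.t0 <= T0_BAND[1]:
            warnings.warn(
                f"t0={self.t0} is outside the empirical band {T0_BAND}; "
                "separability of nuclei from stains is not guaranteed",
                stacklevel=2,
            )
        if self.min_nucleus_area_px < 1:
            raise ValueError("min_nucleus_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass(frozen=True)
class LabeledMask:
    """Connected-component labeling of a binary mask.

    ``labels`` holds integers in the contiguous set {0, 1, ..., n_labels}
    with 0 meaning background; positive labels are ordered by the raster-scan
    position of each component's first pixel.
    """

    labels: np.ndarray
    n_labels: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def areas(self) -> np.ndarray:
        """Pixel count per positive label (index 0 unused, set to 0)."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)
        counts[0] = 0
        return counts


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError(f"expected (H, W, 3) uint8 RGB array, got {img.shape} {img.dtype}")
    return img


def bg_difference(img: np.ndarray) -> np.ndarray:
    """Saturated blue-minus-green difference map.

    Per pixel: ``max(B - G, 0)``, returned as uint8 with the input's shape.
    Saturating (not modular) subtraction is deliberate: wrap-around would
    promote pink regions (G > B) to bright foreground.
    """
    img = _as_rgb(img)
    b = img[..., 2].astype(np.int16)
    g = img[..., 1].astype(np.int16)
    return np.maximum(b - g, 0).astype(np.uint8)


def binarize(diff: np.ndarray, params: SegmentationParams | int) -> np.ndarray:
    """Threshold a difference map: foreground (1) iff ``diff >= t0``."""
    t0 = params.t0 if isinstance(params, SegmentationParams) else int(params)
    diff = np.asarray(diff)
    if diff.ndim != 2:
        raise ValueError("difference map must be 2-D")
    return (diff >= t0).astype(np.uint8)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _relabel_raster_order(labels: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """Remap positive labels to 1..n ordered by first raster-scan pixel."""
    if n == 0:
        return labels, 0
    flat = labels.ravel()
    values, first = np.unique(flat, return_index=True)
    order = np.argsort(first)
    remap = np.zeros(int(values.max()) + 1, dtype=labels.dtype)
    nxt = 0
    for idx in order:
        v = int(values[idx])
        if v == 0:
            continue
        nxt += 1
        remap[v] = nxt
    return remap[labels], nxt


def label_regions(mask: np.ndarray, connectivity: int = 8) -> LabeledMask:
    """Label connected foreground components of a {0,1} mask.

    Labels are contiguous from 1 and ordered by each component's first pixel
    in raster-scan order, so the labeling is a pure function of the mask.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.size and not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must contain only 0/1 values")
    raw, n = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    labels, n = _relabel_raster_order(raw.astype(np.int32), int(n))
    return LabeledMask(labels=labels, n_labels=n)


def size_filter(labeled: LabeledMask, min_area: int) -> LabeledMask:
    """Drop components with area < ``min_area`` (inclusive boundary survives).

    Survivors are relabeled contiguously, preserving their raster order.  No
    background pixel ever gains foreground status.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    counts = np.bincount(labeled.labels.ravel(), minlength=labeled.n_labels + 1)
    keep = counts >= min_area
    keep[0] = False
    remap = np.zeros(labeled.n_labels + 1, dtype=labeled.labels.dtype)
    remap[keep] = np.arange(1, int(keep.sum()) + 1, dtype=labeled.labels.dtype)
    return LabeledMask(labels=remap[labeled.labels], n_labels=int(keep.sum()))
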