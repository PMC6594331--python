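"""Cytoplasm-ratio artifact rejection.

Dye debris can match nuclear color and size and survive every thresholding
stage.  Real leukocytes, however, carry cytoplasm around the nucleus: the
ratio of cytoplasm area to nucleus area of a genuine cell stays at or above
an empirical floor (0.26).  Objects below the floor are flagged as artifacts.

Cytoplasm is recovered inside a region of interest around the nucleus from
Otsu-thresholded saturation (S) and blue (B) channels.  Two combination
rules are available:

``sb_union`` (default)
    whole cell = (S above threshold) OR (B above threshold), restricted to
    the connected component(s) touching the nucleus.  S isolates the heavily
    dyed nucleus, B captures the blue-tinted cytoplasm; their union covers
    the whole cell.
``sb_intersection``
    whole cell = (S above threshold) AND (B above threshold).  Kept for
    comparison; with realistic palettes the saturation threshold tends to
    sit above pale cytoplasm, so the intersection collapses to the nucleus
    and under-reports cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grouping import BBox
from .sab_baseline import histogram256, otsu_threshold, rgb_to_saturation

CYTO_METHODS = ("sb_union", "sb_intersection")


@dataclass(frozen=True)
class ArtifactParams:
    """Artifact-rejection parameters.

    ``ratio_min`` is the cytoplasm/nucleus area-ratio floor (strict: an
    object is an artifact iff its ratio is *smaller than* the floor, so a
    ratio of exactly 0.26 is kept).  ``roi_margin_factor`` scales the
    nucleus bbox half-extents to obtain the analysis window.
    """

    ratio_min: float = 0.26
    # 2.0 (not a tighter 1.5): the Otsu split inside the ROI needs a real
    # background class, which thick-cytoplasm cells otherwise crowd out.
    roi_margin_factor: float = 2.0
    cyto_method: str = "sb_union"

    def __post_init__(self) -> None:
        if self.ratio_min <= 0:
            raise ValueError("ratio_min must be > 0")
        if self.roi_margin_factor < 1.0:
            raise ValueError("roi_margin_factor must be >= 1")
        if self.cyto_method not in CYTO_METHODS:
            raise ValueError(f"cyto_method must be one of {CYTO_METHODS}")


@dataclass(frozen=True)
class CytoplasmSegmentation:
    """Whole-cell and cytoplasm masks (full-size, support confined to the
    ROI) plus the cytoplasm pixel count."""

    cell_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    cyto_area_px: int
    roi: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open


def expand_roi(
    bbox: BBox, shape: tuple[int, int], factor: float
) -> tuple[int, int, int, int]:
    """Grow a nucleus bbox by ``factor`` about its center, clipped to the
    image; returns half-open (row0, row1, col0, col1)."""
    half_w = (bbox.x_r - bbox.x_l + 1) / 2.0
    half_h = (bbox.y_b - bbox.y_t + 1) / 2.0
    cx = (bbox.x_l + bbox.x_r) / 2.0
    cy = (bbox.y_t + bbox.y_b) / 2.0
    c0 = max(0, int(np.floor(cx - factor * half_w)))
    c1 = min(shape[1], int(np.ceil(cx + factor * half_w)) + 1)
    r0 = max(0, int(np.floor(cy - factor * half_h)))
    r1 = min(shape[0], int(np.ceil(cy + factor * half_h)) + 1)
    return r0, r1, c0, c1


def global_channel_thresholds(img: np.ndarray) -> tuple[int | None, int | None]:
    """Full-image Otsu thresholds for (S, B); None marks a degenerate channel.

    Precompute once per image when running many nuclei through
    :func:`segment_cytoplasm`.
    """
    img = np.asarray(img)
    out = []
    for channel in (rgb_to_saturation(img), img[..., 2]):
        res = otsu_threshold(histogram256(channel))
        out.append(None if res.degenerate else res.threshold)
    return out[0], out[1]


def segment_cytoplasm(
    img: np.ndarray,
    nucleus_mask: np.ndarray,
    roi: tuple[int, int, int, int],
    params: ArtifactParams | None = None,
    thresholds: tuple[int | None, int | None] | None = None,
) -> CytoplasmSegmentation:
    """Segment the cytoplasm surrounding a nucleus inside ``roi``.

    The whole-cell mask is built from Otsu-binarized S and B channels
    (combined per ``params.cyto_method``), always includes the nucleus, and
    is restricted to the connected component(s) containing nucleus pixels.
    Cytoplasm = cell minus nucleus.  The Otsu thresholds are estimated on
    the full-image histograms - where the background mode dominates - and
    applied inside the ROI; a window-local histogram degrades whenever
    neighboring cells crowd out the background class.  Degenerate channels
    (constant, so Otsu is vacuous) yield zero cytoplasm rather than an
    exception.
    """
    params = params or ArtifactParams()
    img = np.asarray(img)
    nucleus_mask = np.asarray(nucleus_mask).astype(bool)
    r0, r1, c0, c1 = roi
    sub = img[r0:r1, c0:c1]
    nuc = nucleus_mask[r0:r1, c0:c1]

    if thresholds is None:
        thresholds = global_channel_thresholds(img)
    t_s, t_b = thresholds
    sat = rgb_to_saturation(sub)
    blue = sub[..., 2]

    def _fg(window: np.ndarray, t: int | None) -> np.ndarray:
        if t is None:
            return np.zeros(window.shape, dtype=bool)
        return window > t

    s_fg = _fg(sat, t_s)
    b_fg = _fg(blue, t_b)
    if params.cyto_method == "sb_union":
        cell = s_fg | b_fg
    else:
        cell = s_fg & b_fg
    cell |= nuc

    # keep only component(s) of the cell mask that touch the nucleus
    labels, n = ndimage.label(cell, structure=ndimage.generate_binary_structure(2, 2))
    if n > 0:
        touching = np.unique(labels[nuc])
        touching = touching[touching > 0]
        cell = np.isin(labels, touching)
    cyto = cell & ~nuc

    cell_full = np.zeros(nucleus_mask.shape, dtype=bool)
    cyto_full = np.zeros(nucleus_mask.shape, dtype=bool)
    cell_full[r0:r1, c0:c1] = cell
    cyto_full[r0:r1, c0:c1] = cyto
    return CytoplasmSegmentation(
        cell_mask=cell_full,
        cytoplasm_mask=cyto_full,
        cyto_area_px=int(cyto.sum()),
        roi=roi,
    )


def is_artifact(
    cyto_area_px: int, nucleus_area_px: int, params: ArtifactParams | None = None
) -> tuple[bool, float]:
    """Apply the area-ratio rule; returns (flag, ratio).

    The comparison is strict: ratio < ratio_min flags an artifact, a ratio
    exactly at the floor is kept.
    """
    params = params or ArtifactParams()
    if nucleus_area_px < 1:
        raise ValueError("nucleus_area_px must be >= 1")
    if cyto_area_px < 0:
        raise ValueError("cyto_area_px must be >= 0")
    ratio = cyto_area_px / nucleus_area_px
    return ratio < params.ratio_min, ratio
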