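"""Otsu thresholding and the saturation-and-blue (SAB) comparator.

The comparator segments nuclei by Otsu-thresholding the saturation channel
and the blue channel independently, intersecting the above-threshold sides,
and size-filtering the result.  It exists so the B-G method can be scored
against a conventional Otsu-based approach on the same synthetic scenes; the
Otsu primitive is also reused by the artifact filter's cytoplasm step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bg_core import label_regions, size_filter


@dataclass(frozen=True)
class OtsuResult:
    """Threshold maximizing between-class variance; ``degenerate`` marks a
    single-valued histogram (where any split is vacuous)."""

    threshold: int
    degenerate: bool


def histogram256(values: np.ndarray) -> np.ndarray:
    """256-bin histogram of an 8-bit channel."""
    values = np.asarray(values)
    if values.size and (values.min() < 0 or values.max() > 255):
        raise ValueError("values must be in [0, 255]")
    return np.bincount(values.ravel().astype(np.int64), minlength=256)[:256]


def otsu_threshold(hist: np.ndarray) -> OtsuResult:
    """Exact Otsu threshold over a 256-bin histogram.

    Maximizes the between-class variance of the split {<= t} vs {> t} using
    integer arithmetic (no floating-point ties); the smallest maximizing t is
    returned.  A histogram with a single occupied bin is degenerate and
    returns that bin's index.
    """
    counts = [int(c) for c in np.asarray(hist)]
    if len(counts) != 256:
        raise ValueError("histogram must have 256 bins")
    if any(c < 0 for c in counts):
        raise ValueError("histogram counts must be non-negative")
    total = sum(counts)
    if total < 1:
        raise ValueError("histogram is empty")
    nonzero = [i for i, c in enumerate(counts) if c]
    if len(nonzero) == 1:
        return OtsuResult(threshold=nonzero[0], degenerate=True)

    weighted_total = sum(i * c for i, c in enumerate(counts))
    best_t = 0
    best_num = -1  # between-class variance as best_num / best_den
    best_den = 1
    w0 = 0
    s0 = 0
    for t in range(255):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        s1 = weighted_total - s0
        # w0*w1*(mu0-mu1)^2 == (s0*w1 - s1*w0)^2 / (w0*w1)
        num = (s0 * w1 - s1 * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:  # strict: keeps smallest t on ties
            best_num, best_den, best_t = num, den, t
    return OtsuResult(threshold=best_t, degenerate=False)


def rgb_to_saturation(img: np.ndarray) -> np.ndarray:
    """HSV-style saturation on the 0..255 integer scale.

    S = 0 where max(R,G,B) = 0, else round(255 * (max - min) / max) with
    exact half-up integer rounding; the whole pipeline stays 8-bit.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    mx = img.max(axis=2).astype(np.int64)
    mn = img.min(axis=2).astype(np.int64)
    sat = np.zeros(mx.shape, dtype=np.uint8)
    pos = mx > 0
    # half-up rounding of 255*(mx-mn)/mx in pure integer arithmetic
    sat[pos] = ((510 * (mx[pos] - mn[pos]) + mx[pos]) // (2 * mx[pos])).astype(np.uint8)
    return sat


def segment_nucleus_sab(
    img: np.ndarray, min_nucleus_area_px: int = 500, connectivity: int = 8
) -> np.ndarray:
    """SAB nucleus mask: Otsu(S) above-threshold AND Otsu(B) above-threshold,
    size-filtered with the shared minimum nucleus area.  Returns a {0,1} mask.
    """
    sat = rgb_to_saturation(img)
    blue = np.asarray(img)[..., 2]
    t_s = otsu_threshold(histogram256(sat)).threshold
    t_b = otsu_threshold(histogram256(blue)).threshold
    fg = ((sat > t_s) & (blue > t_b)).astype(np.uint8)
    labeled = label_regions(fg, connectivity=connectivity)
    filtered = size_filter(labeled, min_nucleus_area_px)
    return (filtered.labels > 0).astype(np.uint8)
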