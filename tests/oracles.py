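"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they verify: flood fill by
explicit BFS, projections by coordinate min/max, Otsu by Fraction-exact
per-split class statistics, grouping by an explicit transitive closure, and
matching by exhaustive assignment search.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import permutations

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Connected components as pixel sets, via BFS, in raster order of the
    first pixel of each component."""
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    comp.add((cr, cc))
                    for dr, dc in steps:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                comps.append(comp)
    return comps


def minmax_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(x_l, x_r, y_t, y_b) by coordinate min/max."""
    rows, cols = np.nonzero(mask)
    return int(cols.min()), int(cols.max()), int(rows.min()), int(rows.max())


def otsu_exhaustive(hist) -> int:
    """Smallest t maximizing w0*w1*(mu0-mu1)^2 over all 256 splits, with
    Fraction-exact arithmetic and per-split direct summation over the
    occupied bins."""
    bins = [(i, int(c)) for i, c in enumerate(hist) if c]
    best_t, best_score = 0, Fraction(-1)
    for t in range(256):
        lo = [(i, c) for i, c in bins if i <= t]
        hi = [(i, c) for i, c in bins if i > t]
        w0 = sum(c for _, c in lo)
        w1 = sum(c for _, c in hi)
        if w0 == 0 or w1 == 0:
            continue
        mu0 = Fraction(sum(i * c for i, c in lo), w0)
        mu1 = Fraction(sum(i * c for i, c in hi), w1)
        score = Fraction(w0) * Fraction(w1) * (mu0 - mu1) ** 2
        if score > best_score:
            best_score, best_t = score, t
    return best_t


def saturation_exact(r: int, g: int, b: int) -> int:
    """Half-up-rounded 255*(max-min)/max via rational arithmetic."""
    mx, mn = max(r, g, b), min(r, g, b)
    if mx == 0:
        return 0
    frac = Fraction(255 * (mx - mn), mx) + Fraction(1, 2)
    return int(frac) if frac.denominator == 1 else frac.numerator // frac.denominator


def closure_partition(centroids, areas, s0, d0) -> list[frozenset[int]]:
    """Grouping oracle: repeated pairwise merging to a fixed point."""
    n = len(centroids)
    small = [i for i in range(n) if areas[i] <= s0]
    groups: list[set[int]] = [{i} for i in small]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    np.hypot(centroids[a][0] - centroids[b][0],
                             centroids[a][1] - centroids[b][1]) <= d0
                    for a in groups[i] for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    groups.extend({i} for i in range(n) if areas[i] > s0)
    return sorted((frozenset(g) for g in groups), key=min)


def best_assignment(truth_boxes, det_centers) -> int:
    """Maximum number of one-to-one center-in-box matches, by exhaustive
    search over detection orderings (small instances only)."""
    n_t = len(truth_boxes)
    best = 0
    for order in permutations(range(len(det_centers))):
        used = [False] * n_t
        count = 0
        for di in order:
            x, y = det_centers[di]
            for ti, (x_l, x_r, y_t, y_b) in enumerate(truth_boxes):
                if not used[ti] and x_l <= x <= x_r and y_t <= y <= y_b:
                    used[ti] = True
                    count += 1
                    break
        best = max(best, count)
    return best
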