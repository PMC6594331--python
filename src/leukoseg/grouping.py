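"""Lobe grouping and projection-based nucleus localization.

A multilobed nucleus (typically a neutrophil's) may segment into several
disconnected regions.  Regions no larger than ``s0_px`` are candidate lobes;
two candidates belong to the same nucleus when their centroids lie within
``d0_px`` of each other, extended transitively so that a chain of nearby
lobes forms one nucleus.  Regions larger than ``s0_px`` are whole nuclei on
their own and are exempt from merging.

Each resulting group is localized by projecting its binary mask onto the two
axes: the nonzero extents of the column/row projections give the bounding
box, whose integer midpoint is the reported center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bg_core import LabeledMask


@dataclass(frozen=True)
class GroupingParams:
    """Lobe-grouping parameters.

    ``s0_px`` is the maximum area of a region that can be a lobe of a larger
    nucleus; ``d0_px`` is the maximum centroid-to-centroid Euclidean distance
    (inclusive) for two lobes of the same nucleus.  Defaults are tuned to the
    simulator's geometry at a nominal 1024x768 capture and are configurable.
    """

    s0_px: int = 2500
    d0_px: float = 60.0

    def __post_init__(self) -> None:
        if self.s0_px < 1:
            raise ValueError("s0_px must be >= 1")
        if self.d0_px <= 0:
            raise ValueError("d0_px must be > 0")


@dataclass(frozen=True)
class Region:
    """One labeled connected region: area, centroid and member pixels.

    ``pixels`` is a pair of parallel arrays (rows, cols); the centroid is the
    arithmetic mean of the member coordinates, expressed as (x=col, y=row).
    """

    label: int
    area_px: int
    centroid_x: float
    centroid_y: float
    pixels: tuple[np.ndarray, np.ndarray] = field(repr=False)


@dataclass(frozen=True)
class BBox:
    """Closed, 0-based bounding box with integer midpoint center.

    x is the column index, y the row index (y grows downward).  The box is
    inclusive on all sides, so ``w = x_r - x_l`` is 0 for a single column.
    """

    x_l: int
    x_r: int
    y_t: int
    y_b: int
    x_c: int
    y_c: int
    w: int
    h: int

    def contains(self, x: float, y: float) -> bool:
        return self.x_l <= x <= self.x_r and self.y_t <= y <= self.y_b


@dataclass(frozen=True)
class NucleusDetection:
    """One located nucleus: bbox, size, lobe count and artifact status."""

    x_l: int
    x_r: int
    y_t: int
    y_b: int
    x_c: int
    y_c: int
    w: int
    h: int
    area_px: int
    n_lobes: int
    is_artifact: bool
    cyto_nucleus_ratio: float
    member_labels: tuple[int, ...] = ()

    #: Serialized field order for CSV/JSON records.
    RECORD_FIELDS = (
        "x_l", "x_r", "y_t", "y_b", "x_c", "y_c", "w", "h",
        "area_px", "n_lobes", "is_artifact", "cyto_nucleus_ratio",
    )

    def to_record(self) -> dict:
        return {name: getattr(self, name) for name in self.RECORD_FIELDS}

    @property
    def bbox(self) -> BBox:
        return BBox(self.x_l, self.x_r, self.y_t, self.y_b,
                    self.x_c, self.y_c, self.w, self.h)


def extract_regions(labeled: LabeledMask) -> list[Region]:
    """One :class:`Region` per positive label, with exact area and centroid."""
    rows, cols = np.nonzero(labeled.labels)
    vals = labeled.labels[rows, cols]
    regions: list[Region] = []
    for lab in range(1, labeled.n_labels + 1):
        sel = vals == lab
        r = rows[sel]
        c = cols[sel]
        if r.size == 0:
            raise ValueError(f"label {lab} has no pixels (labels not contiguous?)")
        regions.append(
            Region(
                label=lab,
                area_px=int(r.size),
                centroid_x=float(c.mean()),
                centroid_y=float(r.mean()),
                pixels=(r, c),
            )
        )
    return regions


def group_lobes(regions: Sequence[Region], params: GroupingParams) -> list[list[Region]]:
    """Partition regions into nuclei.

    Regions with area > ``s0_px`` are singleton groups (they are whole,
    non-lobular nuclei and never merge).  Among the rest, two regions share a
    group iff they are connected by a chain of pairwise centroid distances
    <= ``d0_px`` (single-linkage transitive closure; ties at exactly d0
    merge).  The partition is independent of the input order: groups are
    returned sorted by their smallest member label, members sorted by label.
    """
    small = [r for r in regions if r.area_px <= params.s0_px]
    large = [r for r in regions if r.area_px > params.s0_px]

    parent = list(range(len(small)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    d2 = params.d0_px * params.d0_px
    for i in range(len(small)):
        for j in range(i + 1, len(small)):
            dx = small[i].centroid_x - small[j].centroid_x
            dy = small[i].centroid_y - small[j].centroid_y
            if dx * dx + dy * dy <= d2:
                union(i, j)

    by_root: dict[int, list[Region]] = {}
    for i, region in enumerate(small):
        by_root.setdefault(find(i), []).append(region)

    groups = [sorted(g, key=lambda r: r.label) for g in by_root.values()]
    groups.extend([r] for r in large)
    groups.sort(key=lambda g: g[0].label)
    return groups


def project_bbox(group_mask: np.ndarray) -> BBox:
    """Bounding box of a binary mask via axis projections.

    The column projection's first/last nonzero entries give x_l/x_r, the row
    projection's give y_t/y_b; the center is the floor of the midpoint.
    """
    group_mask = np.asarray(group_mask)
    if group_mask.ndim != 2:
        raise ValueError("group mask must be 2-D")
    col_proj = group_mask.any(axis=0)
    row_proj = group_mask.any(axis=1)
    xs = np.flatnonzero(col_proj)
    ys = np.flatnonzero(row_proj)
    if xs.size == 0:
        raise ValueError("cannot localize an empty mask")
    x_l, x_r = int(xs[0]), int(xs[-1])
    y_t, y_b = int(ys[0]), int(ys[-1])
    return BBox(
        x_l=x_l, x_r=x_r, y_t=y_t, y_b=y_b,
        x_c=(x_l + x_r) // 2, y_c=(y_t + y_b) // 2,
        w=x_r - x_l, h=y_b - y_t,
    )


def group_mask(group: Iterable[Region], shape: tuple[int, int]) -> np.ndarray:
    """Render the union of a group's member pixels as a boolean mask."""
    mask = np.zeros(shape, dtype=bool)
    for region in group:
        rows, cols = region.pixels
        mask[rows, cols] = True
    return mask


def locate_nuclei(labeled: LabeledMask, params: GroupingParams) -> list[NucleusDetection]:
    """Group lobes and localize each nucleus (no artifact information yet).

    Detections carry ``is_artifact=False`` and ratio 0.0; the artifact filter
    fills those in downstream.
    """
    regions = extract_regions(labeled)
    detections = []
    for group in group_lobes(regions, params):
        mask = group_mask(group, labeled.shape)
        box = project_bbox(mask)
        detections.append(
            NucleusDetection(
                x_l=box.x_l, x_r=box.x_r, y_t=box.y_t, y_b=box.y_b,
                x_c=box.x_c, y_c=box.y_c, w=box.w, h=box.h,
                area_px=sum(r.area_px for r in group),
                n_lobes=len(group),
                is_artifact=False,
                cyto_nucleus_ratio=0.0,
                member_labels=tuple(r.label for r in group),
            )
        )
    return detections
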