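"""Synthetic stained-smear micrograph generator with ground truth.

Scenes emulate the color statistics of Wright-Giemsa stained peripheral
blood smears as seen by the B-G statistic:

* nucleus interiors (and platelets, and nucleus-colored artifacts) carry a
  pre-noise B-G difference in [119, 160] (within the documented [115, 180]
  band, so post-noise values stay strictly above 110);
* dye-precipitate "stains" carry B-G in [12, 38] (< 50 post-noise);
* erythrocytes and background are pink/neutral with B-G <= 10;
* cytoplasm is pale blue with a small B-G (< 30 post-noise).

Pixel noise is Gaussian with configurable sigma but *truncated* at +/-4
intensity units per channel, which is what makes the separability bands
deterministic rather than merely probable.  The illumination shift is a
single offset added to all three channels, so it cancels exactly in B-G.

Nuclei are unions of 1-5 elliptical lobes, either fused into one connected
region or deliberately split into disjoint lobes whose consecutive centroid
distances stay within the default grouping distance - both variants exercise
the lobe-grouping rule.  Planted nuclei are pairwise non-overlapping, and
lobe centroids of distinct nucleus-like objects are kept >= 80 px apart so
that default grouping parameters never merge two different cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._errors import CapacityError

CLASSES = ("leukocyte", "platelet", "stain", "erythrocyte", "artifact")
LEUKOCYTE_TYPES = ("Neu", "Lym", "Mon", "Eos", "Bas")
#: sampling weights for leukocyte subtype labels (typical differential)
LEUKOCYTE_TYPE_WEIGHTS = (0.60, 0.26, 0.07, 0.05, 0.02)

#: per-channel noise truncation bound (intensity units)
NOISE_CLIP = 4
#: minimum separation between lobe centroids of distinct nucleus-like objects
MIN_NUCLEUS_SEP = 80.0
#: minimum pixel clearance between distinct planted objects
CLEARANCE = 3

BACKGROUND = (172, 165, 168)  # B-G = 3

_NOMINAL_MAX_AREA = {
    "leukocyte": 9000.0,  # whole cell including cytoplasm
    "platelet": 160.0,
    "stain": 1500.0,
    "erythrocyte": 650.0,
    "artifact": 1700.0,
}


@dataclass(frozen=True)
class SceneParams:
    """Parameters for one synthetic scene (deterministic given ``seed``)."""

    width: int = 1024
    height: int = 768
    n_leukocytes: int = 5
    lobe_count_range: tuple[int, int] = (1, 5)
    n_platelets: int = 15
    n_stains: int = 2
    n_erythrocytes: int = 30
    n_artifacts: int = 0
    clumping: str = "none"
    illumination_shift: int = 0
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 96 or self.height < 96:
            raise ValueError("scene must be at least 96x96")
        lo, hi = self.lobe_count_range
        if not (1 <= lo <= hi <= 5):
            raise ValueError("lobe_count_range must satisfy 1 <= lo <= hi <= 5")
        if self.clumping not in ("none", "adjacent_nonoverlapping"):
            raise ValueError(f"unknown clumping mode {self.clumping!r}")
        if abs(self.illumination_shift) > 20:
            raise ValueError("illumination_shift must be within [-20, 20]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("n_leukocytes", "n_platelets", "n_stains",
                     "n_erythrocytes", "n_artifacts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        budget = sum(
            getattr(self, f"n_{cls}s" if cls != "erythrocyte" else "n_erythrocytes")
            * _NOMINAL_MAX_AREA[cls]
            for cls in CLASSES
        )
        if budget > 0.5 * self.width * self.height:
            raise CapacityError(
                f"requested objects need ~{budget:.0f} px but only half of "
                f"{self.width * self.height} px may be occupied"
            )


@dataclass(frozen=True)
class MaskPatch:
    """A boolean mask patch plus its (row, col) offset in the scene."""

    mask: np.ndarray = field(repr=False)
    offset: tuple[int, int]

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.nonzero(self.mask)
        return rows + self.offset[0], cols + self.offset[1]

    def centroid(self) -> tuple[float, float]:
        rows, cols = self.coords()
        return float(cols.mean()), float(rows.mean())  # (x, y)

    def paint(self, canvas: np.ndarray, color: tuple[int, int, int]) -> None:
        r0, c0 = self.offset
        h, w = self.mask.shape
        canvas[r0:r0 + h, c0:c0 + w][self.mask] = color

    def full(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.mask.shape
        out[r0:r0 + h, c0:c0 + w] = self.mask
        return out


@dataclass
class SceneObject:
    """Ground truth for one planted object."""

    cls: str
    lobe_masks: list[MaskPatch]
    nucleus_area_px: int
    cytoplasm_area_px: int
    bbox: tuple[int, int, int, int]  # (x_l, x_r, y_t, y_b), closed
    center: tuple[int, int]          # (x_c, y_c), INT midpoint of the bbox
    subtype: str | None = None


@dataclass
class SceneTruth:
    """Ground truth for a whole scene."""

    width: int
    height: int
    objects: list[SceneObject]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def of_class(self, cls: str) -> list[SceneObject]:
        return [o for o in self.objects if o.cls == cls]

    @property
    def leukocytes(self) -> list[SceneObject]:
        return self.of_class("leukocyte")

    def class_mask(self, *classes: str) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for obj in self.objects:
            if obj.cls in classes:
                for patch in obj.lobe_masks:
                    rows, cols = patch.coords()
                    out[rows, cols] = True
        return out


@dataclass(frozen=True)
class PaletteReport:
    """Post-noise separability audit of a generated scene."""

    min_nucleus_diff: int
    max_stain_diff: int
    max_other_diff: int
    compliant: bool


def _union_bbox(patches: list[MaskPatch]) -> tuple[tuple[int, int, int, int], tuple[int, int]]:
    rows = np.concatenate([p.coords()[0] for p in patches])
    cols = np.concatenate([p.coords()[1] for p in patches])
    x_l, x_r = int(cols.min()), int(cols.max())
    y_t, y_b = int(rows.min()), int(rows.max())
    return (x_l, x_r, y_t, y_b), ((x_l + x_r) // 2, (y_t + y_b) // 2)


def _ellipse_mask(a: float, b: float, theta: float) -> np.ndarray:
    """Tight boolean patch of a rotated ellipse with semi-axes a (x), b (y)."""
    n = int(np.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    ca, sa = np.cos(theta), np.sin(theta)
    u = xx * ca + yy * sa
    v = -xx * sa + yy * ca
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def _disk_mask(r: float) -> np.ndarray:
    return _ellipse_mask(r, r, 0.0)


# ---------------------------------------------------------------------------
# palettes (all channel values kept within [24, 228] so that the +/-20
# illumination shift plus +/-4 truncated noise never clips at 0 or 255)

def _nucleus_color(rng) -> tuple[int, int, int]:
    diff = int(rng.integers(119, 161))
    b = int(rng.integers(max(185, diff + 24), 221))
    g = b - diff
    r = int(rng.integers(60, 121))
    return (r, g, b)


def _cyto_color(rng) -> tuple[int, int, int]:
    g = int(rng.integers(178, 191))
    b = g + int(rng.integers(12, 19))
    r = int(rng.integers(168, 177))
    return (r, g, b)


def _ery_color(rng) -> tuple[int, int, int]:
    g = int(rng.integers(138, 151))
    b = g + int(rng.integers(2, 9))
    r = int(rng.integers(172, 187))
    return (r, g, b)


def _ery_inner_color(rng) -> tuple[int, int, int]:
    g = int(rng.integers(158, 166))
    b = g + int(rng.integers(1, 6))
    r = int(rng.integers(172, 181))
    return (r, g, b)


def _stain_color(rng) -> tuple[int, int, int]:
    g = int(rng.integers(130, 149))
    b = g + int(rng.integers(12, 39))
    r = int(rng.integers(140, 166))
    return (r, g, b)


# ---------------------------------------------------------------------------
# leukocyte construction (local frame)

_LOCAL = 340  # local canvas side; generously covers a 5-lobe chain plus ring


def _build_lobes(rng, n_lobes: int) -> tuple[list[np.ndarray], str]:
    """Place ``n_lobes`` ellipses on a local canvas.

    Returns per-lobe boolean canvases and the variant: "fused" lobes overlap
    into one connected region; "split" lobes are pairwise >= CLEARANCE apart
    with consecutive centroid distances <= 50 px (inside the default
    grouping distance).
    """
    variant = "fused" if n_lobes == 1 or rng.random() < 0.5 else "split"
    if variant == "split":
        axes_lo, axes_hi = 14, 19
    else:
        axes_lo, axes_hi = 16, 26

    lobes: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    amins: list[float] = []
    amaxs: list[float] = []
    center = np.array([_LOCAL / 2.0, _LOCAL / 2.0])  # (row, col)
    occupied = np.zeros((_LOCAL, _LOCAL), dtype=bool)

    for k in range(n_lobes):
        for _ in range(200):
            a = float(rng.integers(axes_lo, axes_hi + 1))
            b = float(rng.integers(axes_lo, axes_hi + 1))
            theta = float(rng.uniform(0, np.pi))
            patch = _ellipse_mask(a, b, theta)
            if k == 0:
                pos = center
            else:
                prev = centers[-1]
                ang = rng.uniform(0, 2 * np.pi)
                if variant == "fused":
                    dist = rng.uniform(0.5, 0.75) * (amins[-1] + min(a, b))
                else:
                    lo = amaxs[-1] + max(a, b) + CLEARANCE + 2
                    if lo >= 50:
                        continue
                    dist = rng.uniform(lo, 50.0)
                pos = prev + dist * np.array([np.sin(ang), np.cos(ang)])
            r0 = int(round(pos[0])) - patch.shape[0] // 2
            c0 = int(round(pos[1])) - patch.shape[1] // 2
            if r0 < 30 or c0 < 30 or r0 + patch.shape[0] > _LOCAL - 30 \
                    or c0 + patch.shape[1] > _LOCAL - 30:
                continue
            canvas = np.zeros((_LOCAL, _LOCAL), dtype=bool)
            canvas[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] = patch
            if variant == "split" and k > 0:
                grown = ndimage.binary_dilation(canvas, iterations=CLEARANCE)
                if (grown & occupied).any():
                    continue
            rows, cols = np.nonzero(canvas)
            centers.append(np.array([rows.mean(), cols.mean()]))
            amins.append(min(a, b))
            amaxs.append(max(a, b))
            lobes.append(canvas)
            occupied |= canvas
            break
        else:
            raise CapacityError("could not place a nucleus lobe")
    return lobes, variant


def _build_leukocyte(rng, lobe_range: tuple[int, int]) -> dict:
    """Build a leukocyte (lobes + cytoplasm ring) in a tight local frame."""
    n_lobes = int(rng.integers(lobe_range[0], lobe_range[1] + 1))
    lobes, variant = _build_lobes(rng, n_lobes)
    nucleus = np.logical_or.reduce(lobes)
    target_ratio = rng.uniform(0.5, 0.75)
    dist = ndimage.distance_transform_edt(~nucleus)
    nucleus_area = int(nucleus.sum())
    cell = nucleus
    for t in range(3, 28):
        cell = dist <= t
        ratio = (int(cell.sum()) - nucleus_area) / nucleus_area
        if ratio >= target_ratio:
            break
    # crop to tight cell bbox with a 2 px border
    rows = np.flatnonzero(cell.any(axis=1))
    cols = np.flatnonzero(cell.any(axis=0))
    r0, r1 = rows[0] - 2, rows[-1] + 3
    c0, c1 = cols[0] - 2, cols[-1] + 3
    crop = np.s_[r0:r1, c0:c1]
    return {
        "lobes": [lb[crop] for lb in lobes],
        "nucleus": nucleus[crop],
        "cell": cell[crop],
        "cyto": (cell & ~nucleus)[crop],
        "variant": variant,
        "nucleus_color": _nucleus_color(rng),
        "cyto_color": _cyto_color(rng),
    }


# ---------------------------------------------------------------------------
# scene assembly

class _Placer:
    """Rejection-sampling placement with a dilated occupancy mask."""

    def __init__(self, rng, height: int, width: int):
        self.rng = rng
        self.height = height
        self.width = width
        self.occupancy = np.zeros((height, width), dtype=bool)
        self.nucleus_centroids: list[tuple[float, float]] = []

    def stamp(self, mask: np.ndarray, r0: int, c0: int) -> None:
        grown = ndimage.binary_dilation(
            np.pad(mask, CLEARANCE), iterations=CLEARANCE
        )
        rr0 = max(0, r0 - CLEARANCE)
        cc0 = max(0, c0 - CLEARANCE)
        gr0 = max(0, CLEARANCE - r0)
        gc0 = max(0, CLEARANCE - c0)
        h = min(self.height - rr0, grown.shape[0] - gr0)
        w = min(self.width - cc0, grown.shape[1] - gc0)
        self.occupancy[rr0:rr0 + h, cc0:cc0 + w] |= grown[gr0:gr0 + h, gc0:gc0 + w]

    def nucleus_sep_ok(self, centroids: list[tuple[float, float]]) -> bool:
        for x, y in centroids:
            for px, py in self.nucleus_centroids:
                if (x - px) ** 2 + (y - py) ** 2 < MIN_NUCLEUS_SEP ** 2:
                    return False
        return True

    def place(self, mask: np.ndarray, tries: int = 300, check=None,
              margin: int = 2) -> tuple[int, int]:
        h, w = mask.shape
        if h > self.height - 2 * margin or w > self.width - 2 * margin:
            raise CapacityError("object larger than scene")
        for _ in range(tries):
            r0 = int(self.rng.integers(margin, self.height - h - margin + 1))
            c0 = int(self.rng.integers(margin, self.width - w - margin + 1))
            if self.occupancy[r0:r0 + h, c0:c0 + w][mask].any():
                continue
            if check is not None and not check(r0, c0):
                continue
            return r0, c0
        raise CapacityError("could not place object after bounded retries")


def _lobe_centroids(lobes: list[np.ndarray], r0: int, c0: int) -> list[tuple[float, float]]:
    out = []
    for lb in lobes:
        rows, cols = np.nonzero(lb)
        out.append((float(cols.mean()) + c0, float(rows.mean()) + r0))
    return out


def _place_leukocytes(params: SceneParams, rng, placer: _Placer,
                      canvas: np.ndarray) -> list[SceneObject]:
    objects: list[SceneObject] = []
    pending = []  # paint cytoplasm first, nuclei on top
    if params.clumping == "adjacent_nonoverlapping":
        pending = _place_clumped(params, rng, placer)
    else:
        for _ in range(params.n_leukocytes):
            spec = _build_leukocyte(rng, params.lobe_count_range)
            cell = spec["cell"]

            def check(r0: int, c0: int, spec=spec) -> bool:
                return placer.nucleus_sep_ok(
                    _lobe_centroids(spec["lobes"], r0, c0)
                )

            r0, c0 = placer.place(cell, check=check, margin=16)
            placer.stamp(cell, r0, c0)
            placer.nucleus_centroids.extend(
                _lobe_centroids(spec["lobes"], r0, c0))
            pending.append((spec, r0, c0))

    for spec, r0, c0 in pending:
        MaskPatch(spec["cyto"], (r0, c0)).paint(canvas, spec["cyto_color"])
    for spec, r0, c0 in pending:
        MaskPatch(spec["nucleus"], (r0, c0)).paint(canvas, spec["nucleus_color"])
        lobe_patches = []
        for lb in spec["lobes"]:
            rows = np.flatnonzero(lb.any(axis=1))
            cols = np.flatnonzero(lb.any(axis=0))
            tight = lb[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
            lobe_patches.append(
                MaskPatch(tight, (r0 + int(rows[0]), c0 + int(cols[0]))))
        bbox, center = _union_bbox(lobe_patches)
        objects.append(
            SceneObject(
                cls="leukocyte",
                lobe_masks=lobe_patches,
                nucleus_area_px=int(spec["nucleus"].sum()),
                cytoplasm_area_px=int(spec["cyto"].sum()),
                bbox=bbox,
                center=center,
                subtype=str(rng.choice(LEUKOCYTE_TYPES, p=LEUKOCYTE_TYPE_WEIGHTS)),
            )
        )
    return objects


def _build_round_cell(rng) -> dict:
    """Single-lobe round leukocyte with a thick ring, used in clump mode.

    The thick cytoplasm lets neighboring cells touch while their nucleus
    centroids stay >= MIN_NUCLEUS_SEP apart.
    """
    a = float(rng.integers(20, 25))
    ring = 24.0  # thick ring: touching neighbors keep nuclei >= MIN_NUCLEUS_SEP apart
    nucleus_patch = _disk_mask(a)
    cell_patch = _disk_mask(a + ring)
    pad = (cell_patch.shape[0] - nucleus_patch.shape[0]) // 2
    nucleus = np.pad(nucleus_patch, pad)
    if nucleus.shape != cell_patch.shape:
        nucleus = np.pad(nucleus, ((0, cell_patch.shape[0] - nucleus.shape[0]),
                                   (0, cell_patch.shape[1] - nucleus.shape[1])))
    return {
        "lobes": [nucleus],
        "nucleus": nucleus,
        "cell": cell_patch,
        "cyto": cell_patch & ~nucleus,
        "variant": "fused",
        "nucleus_color": _nucleus_color(rng),
        "cyto_color": _cyto_color(rng),
        "radius": a + ring,
    }


def _place_clumped(params: SceneParams, rng, placer: _Placer) -> list:
    """Chain leukocytes so neighboring cell masks touch but nuclei stay apart."""
    pending = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    nucleus_masks_grown: list[MaskPatch] = []
    for k in range(params.n_leukocytes):
        spec = _build_round_cell(rng)
        rho = spec["radius"]
        h, w = spec["cell"].shape
        placed = False
        margin = 16  # keep whole cells away from borders so ROIs see background
        for _ in range(400):
            if k == 0:
                r0 = int(rng.integers(margin, params.height - h - margin + 1))
                c0 = int(rng.integers(margin, params.width - w - margin + 1))
                center = np.array([r0 + h / 2.0, c0 + w / 2.0])
            else:
                ang = rng.uniform(0, 2 * np.pi)
                dist = radii[-1] + rho - 3.0  # 3 px ring overlap: touching cells
                center = centers[-1] + dist * np.array([np.sin(ang), np.cos(ang)])
                r0 = int(round(center[0] - h / 2.0))
                c0 = int(round(center[1] - w / 2.0))
                if r0 < margin or c0 < margin or r0 + h > params.height - margin \
                        or c0 + w > params.width - margin:
                    continue
            centroids = _lobe_centroids(spec["lobes"], r0, c0)
            if not placer.nucleus_sep_ok(centroids):
                continue
            # nuclei of different cells must keep pixel clearance
            nuc_patch = MaskPatch(spec["nucleus"], (r0, c0))
            nuc_full_rows, nuc_full_cols = nuc_patch.coords()
            collide = False
            for grown in nucleus_masks_grown:
                gr, gc = grown.offset
                gh, gw = grown.mask.shape
                inside = (
                    (nuc_full_rows >= gr) & (nuc_full_rows < gr + gh)
                    & (nuc_full_cols >= gc) & (nuc_full_cols < gc + gw)
                )
                if inside.any() and grown.mask[
                    nuc_full_rows[inside] - gr, nuc_full_cols[inside] - gc
                ].any():
                    collide = True
                    break
            if collide:
                continue
            placed = True
            break
        if not placed:
            raise CapacityError("could not place clumped leukocyte")
        centers.append(center)
        radii.append(rho)
        placer.nucleus_centroids.extend(centroids)
        nucleus_masks_grown.append(
            MaskPatch(ndimage.binary_dilation(
                np.pad(spec["nucleus"], CLEARANCE), iterations=CLEARANCE),
                (r0 - CLEARANCE, c0 - CLEARANCE))
        )
        placer.stamp(spec["cell"], r0, c0)
        pending.append((spec, r0, c0))
    return pending


def _make_blob(rng, cls: str) -> np.ndarray:
    if cls == "platelet":
        a = float(rng.integers(4, 8))
        b = float(rng.integers(4, 8))
        return _ellipse_mask(a, b, float(rng.uniform(0, np.pi)))
    if cls == "artifact":
        a = float(rng.integers(15, 23))
        b = float(rng.integers(15, 23))
        return _ellipse_mask(a, b, float(rng.uniform(0, np.pi)))
    if cls == "stain":
        parts = []
        base = np.zeros((80, 80), dtype=bool)
        cx = cy = 40
        for _ in range(int(rng.integers(2, 4))):
            a = float(rng.integers(8, 17))
            b = float(rng.integers(8, 17))
            patch = _ellipse_mask(a, b, float(rng.uniform(0, np.pi)))
            dr = int(rng.integers(-8, 9))
            dc = int(rng.integers(-8, 9))
            r0 = cy + dr - patch.shape[0] // 2
            c0 = cx + dc - patch.shape[1] // 2
            base[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] |= patch
        rows = np.flatnonzero(base.any(axis=1))
        cols = np.flatnonzero(base.any(axis=0))
        return base[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    raise ValueError(cls)


def _place_simple(cls: str, count: int, rng, placer: _Placer,
                  canvas: np.ndarray) -> list[SceneObject]:
    objects = []
    for _ in range(count):
        mask = _make_blob(rng, cls)
        nucleus_like = cls in ("artifact",)

        def check(r0: int, c0: int, mask=mask, nucleus_like=nucleus_like) -> bool:
            if not nucleus_like:
                return True
            rows, cols = np.nonzero(mask)
            cx = float(cols.mean()) + c0
            cy = float(rows.mean()) + r0
            return placer.nucleus_sep_ok([(cx, cy)])

        r0, c0 = placer.place(mask, check=check)
        placer.stamp(mask, r0, c0)
        patch = MaskPatch(mask, (r0, c0))
        if nucleus_like:
            placer.nucleus_centroids.append(patch.centroid())
        color = _nucleus_color(rng) if cls in ("platelet", "artifact") \
            else _stain_color(rng)
        patch.paint(canvas, color)
        bbox, center = _union_bbox([patch])
        objects.append(SceneObject(
            cls=cls, lobe_masks=[patch],
            nucleus_area_px=patch.area, cytoplasm_area_px=0,
            bbox=bbox, center=center,
        ))
    return objects


def _place_erythrocytes(count: int, rng, placer: _Placer,
                        canvas: np.ndarray) -> list[SceneObject]:
    objects = []
    for _ in range(count):
        r_out = float(rng.integers(10, 15))
        outer = _disk_mask(r_out)
        inner_patch = _disk_mask(r_out * 0.55)
        pad = (outer.shape[0] - inner_patch.shape[0]) // 2
        inner = np.zeros_like(outer)
        inner[pad:pad + inner_patch.shape[0], pad:pad + inner_patch.shape[1]] = inner_patch
        r0, c0 = placer.place(outer)
        placer.stamp(outer, r0, c0)
        patch = MaskPatch(outer, (r0, c0))
        MaskPatch(outer & ~inner, (r0, c0)).paint(canvas, _ery_color(rng))
        MaskPatch(inner, (r0, c0)).paint(canvas, _ery_inner_color(rng))
        bbox, center = _union_bbox([patch])
        objects.append(SceneObject(
            cls="erythrocyte", lobe_masks=[patch],
            nucleus_area_px=patch.area, cytoplasm_area_px=0,
            bbox=bbox, center=center,
        ))
    return objects


def generate_scene(params: SceneParams) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene; bit-identical for identical params.

    Returns the uint8 RGB image and its :class:`SceneTruth`.
    """
    rng = np.random.default_rng(params.seed)
    canvas = np.empty((params.height, params.width, 3), dtype=np.uint8)
    canvas[...] = BACKGROUND
    placer = _Placer(rng, params.height, params.width)

    objects: list[SceneObject] = []
    objects.extend(_place_leukocytes(params, rng, placer, canvas))
    objects.extend(_place_simple("artifact", params.n_artifacts, rng, placer, canvas))
    objects.extend(_place_simple("platelet", params.n_platelets, rng, placer, canvas))
    objects.extend(_place_simple("stain", params.n_stains, rng, placer, canvas))
    objects.extend(_place_erythrocytes(params.n_erythrocytes, rng, placer, canvas))

    img = canvas.astype(np.int16)
    img += params.illumination_shift
    if params.noise_sigma > 0:
        noise = rng.normal(0.0, params.noise_sigma, size=img.shape)
        noise = np.clip(np.rint(noise), -NOISE_CLIP, NOISE_CLIP).astype(np.int16)
        img += noise
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, SceneTruth(width=params.width, height=params.height, objects=objects)


def check_palette(img: np.ndarray, truth: SceneTruth) -> PaletteReport:
    """Audit a scene against the separability bands by direct inspection.

    Compliant iff every nucleus-colored pixel (leukocyte lobes, platelets,
    artifacts) has B-G > 110 and every stain pixel has B-G < 50 in the final
    (post-noise) image; all remaining pixels must also stay below 50.
    """
    from .bg_core import bg_difference

    diff = bg_difference(img).astype(int)
    nuclei = truth.class_mask("leukocyte", "platelet", "artifact")
    stains = truth.class_mask("stain")
    other = ~(nuclei | stains)
    min_nuc = int(diff[nuclei].min()) if nuclei.any() else 255
    max_stain = int(diff[stains].max()) if stains.any() else 0
    max_other = int(diff[other].max()) if other.any() else 0
    return PaletteReport(
        min_nucleus_diff=min_nuc,
        max_stain_diff=max_stain,
        max_other_diff=max_other,
        compliant=(min_nuc > 110) and (max_stain < 50) and (max_other < 50),
    )


# ---------------------------------------------------------------------------
# serialization

def truth_to_dict(truth: SceneTruth,
                  lobe_mask_files: dict[int, list[str]] | None = None) -> dict:
    objs = []
    for i, obj in enumerate(truth.objects):
        rec = {
            "class": obj.cls,
            "subtype": obj.subtype,
            "nucleus_area_px": obj.nucleus_area_px,
            "cytoplasm_area_px": obj.cytoplasm_area_px,
            "bbox": list(obj.bbox),
            "center": list(obj.center),
        }
        if lobe_mask_files is not None:
            rec["lobe_mask_files"] = lobe_mask_files.get(i, [])
        objs.append(rec)
    return {"width": truth.width, "height": truth.height, "objects": objs}


def truth_from_dict(data: dict) -> SceneTruth:
    """Rebuild a (mask-free) SceneTruth from its JSON form."""
    objects = [
        SceneObject(
            cls=rec["class"],
            lobe_masks=[],
            nucleus_area_px=int(rec["nucleus_area_px"]),
            cytoplasm_area_px=int(rec["cytoplasm_area_px"]),
            bbox=tuple(rec["bbox"]),
            center=tuple(rec["center"]),
            subtype=rec.get("subtype"),
        )
        for rec in data["objects"]
    ]
    return SceneTruth(width=int(data["width"]), height=int(data["height"]),
                      objects=objects)


def scene_gallery(out_dir: str | Path, n: int, seed: int) -> Path:
    """Write ``n`` scenes (PNG + truth JSON + lobe-mask PNGs) spanning lobe
    counts, clumping modes and the illumination range; returns the manifest
    path.  Deterministic for fixed ``seed``."""
    from .image_io import write_mask
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shifts = (-20, -10, 0, 10, 20)
    entries = []
    for i in range(n):
        clumping = "adjacent_nonoverlapping" if i % 4 == 3 else "none"
        params = SceneParams(
            width=512, height=384,
            n_leukocytes=3,
            lobe_count_range=(1, 1 + i % 5),
            n_platelets=6, n_stains=2, n_erythrocytes=10,
            n_artifacts=i % 2,
            clumping=clumping,
            illumination_shift=shifts[i % 5],
            seed=seed + i,
        )
        img, truth = generate_scene(params)
        stem = f"scene_{i:03d}"
        img_file = out_dir / f"{stem}.png"
        iio.imwrite(img_file, img)
        mask_files: dict[int, list[str]] = {}
        for oi, obj in enumerate(truth.objects):
            files = []
            for li, patch in enumerate(obj.lobe_masks):
                mf = out_dir / f"{stem}_obj{oi:02d}_lobe{li}.png"
                write_mask(patch.full(truth.shape).astype(np.uint8), mf)
                files.append(mf.name)
            mask_files[oi] = files
        truth_file = out_dir / f"{stem}_truth.json"
        with open(truth_file, "w") as fh:
            json.dump(truth_to_dict(truth, mask_files), fh, indent=1, sort_keys=True)
            fh.write("\n")
        report = check_palette(img, truth)
        entries.append({
            "image": img_file.name,
            "truth": truth_file.name,
            "seed": params.seed,
            "clumping": params.clumping,
            "illumination_shift": params.illumination_shift,
            "lobe_count_range": list(params.lobe_count_range),
            "palette_compliant": report.compliant,
        })
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"n": n, "seed": seed, "scenes": entries}, fh, indent=1,
                  sort_keys=True)
        fh.write("\n")
    return manifest
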