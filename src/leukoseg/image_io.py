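"""Raster I/O and detection-record serialization.

Coordinate convention (global to the package): x is the column index, y the
row index, both 0-based, with y increasing downward.  A mask pixel at
(row r, col c) maps to (x=c, y=r) in every serialized record.  Bounding
boxes are closed on all sides.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from ._errors import CapacityError, FormatError
from .grouping import NucleusDetection

SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit raster image as an (H, W, 3) uint8 RGB array.

    Grayscale inputs are replicated across channels; an alpha channel is
    dropped.  Non-8-bit inputs are rejected (the whole pipeline is 8-bit).
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format: {path}")
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: only 8-bit images are supported, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: unsupported channel layout {arr.shape}")
    return np.ascontiguousarray(arr)


def write_mask(mask, path: str | Path) -> None:
    """Write a binary or labeled mask as a PNG.

    Binary masks (bool or uint8 with values in {0,1}) are scaled to {0,255}
    and written as 8-bit PNG.  Wider-integer arrays and
    :class:`~leukoseg.bg_core.LabeledMask` instances are written as 16-bit
    PNG holding the raw label values (capacity 65535 labels).
    """
    path = Path(path)
    arr = getattr(mask, "labels", mask)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    if arr.dtype == bool or arr.dtype == np.uint8:
        if arr.size and int(arr.max()) > 1:
            raise ValueError("binary mask contains values outside {0, 1}")
        iio.imwrite(path, (arr.astype(np.uint8) * 255))
    else:
        if arr.size and (int(arr.min()) < 0):
            raise ValueError("labeled mask contains negative labels")
        if arr.size and int(arr.max()) > 65535:
            raise CapacityError("more than 65535 labels cannot be stored in 16-bit PNG")
        iio.imwrite(path, arr.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG written by :func:`write_mask` (uint8 or uint16)."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel mask")
    return arr


def _record_to_row(rec: dict) -> list:
    row = []
    for name in NucleusDetection.RECORD_FIELDS:
        value = rec[name]
        if name == "is_artifact":
            value = int(value)
        row.append(value)
    return row


def write_detections(
    dets: Sequence[NucleusDetection], path: str | Path, format: str = "csv"
) -> None:
    """Serialize detections to CSV or JSON with a stable field order.

    Output is deterministic for fixed input: fields always appear in
    :attr:`NucleusDetection.RECORD_FIELDS` order, floats via ``repr``.
    """
    path = Path(path)
    records = [d.to_record() for d in dets]
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(NucleusDetection.RECORD_FIELDS)
            for rec in records:
                writer.writerow(_record_to_row(rec))
    elif format == "json":
        for rec in records:
            rec["is_artifact"] = bool(rec["is_artifact"])
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def read_detections(path: str | Path) -> list[NucleusDetection]:
    """Parse a detections file written by :func:`write_detections`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
    else:
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh))
    dets = []
    for rec in records:
        dets.append(
            NucleusDetection(
                x_l=int(rec["x_l"]), x_r=int(rec["x_r"]),
                y_t=int(rec["y_t"]), y_b=int(rec["y_b"]),
                x_c=int(rec["x_c"]), y_c=int(rec["y_c"]),
                w=int(rec["w"]), h=int(rec["h"]),
                area_px=int(rec["area_px"]), n_lobes=int(rec["n_lobes"]),
                is_artifact=bool(int(rec["is_artifact"]))
                if not isinstance(rec["is_artifact"], bool)
                else rec["is_artifact"],
                cyto_nucleus_ratio=float(rec["cyto_nucleus_ratio"]),
            )
        )
    return dets
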