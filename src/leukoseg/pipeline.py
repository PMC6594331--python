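"""End-to-end orchestration: difference map -> binarize -> size filter ->
label -> group lobes -> localize -> cytoplasm-ratio artifact check.

The pipeline is a pure function of (image, config): no global state, no
randomness.  Artifact-flagged detections are retained in the output with
``is_artifact=True``; discarding them is the consumer's decision (counting
does honor the flag).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._errors import ConfigError, PipelineStageError
from .artifact_filter import (
    ArtifactParams,
    expand_roi,
    global_channel_thresholds,
    is_artifact,
    segment_cytoplasm,
)
from .bg_core import SegmentationParams, bg_difference, binarize, label_regions, size_filter
from .grouping import GroupingParams, NucleusDetection, group_mask, locate_nuclei
from .sab_baseline import segment_nucleus_sab

log = logging.getLogger(__name__)

#: Debug-stage file names, mirroring the method's canonical stage sequence:
#: captured image, B-G image, binarization, segmented (size-filtered) nuclei,
#: labeled regions.
DEBUG_STAGES = (
    "01_captured",
    "02_bg_difference",
    "03_binarization",
    "04_segmented_nuclei",
    "05_labeled_regions",
)


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    artifact: ArtifactParams = field(default_factory=ArtifactParams)
    method: str = "bg"

    def __post_init__(self) -> None:
        if self.method not in ("bg", "sab"):
            raise ConfigError(f"method must be 'bg' or 'sab', got {self.method!r}")


#: flat config-file keys -> (section dataclass attribute, field name)
_CONFIG_KEYS = {
    "t0": ("segmentation", "t0"),
    "min_nucleus_area_px": ("segmentation", "min_nucleus_area_px"),
    "connectivity": ("segmentation", "connectivity"),
    "s0_px": ("grouping", "s0_px"),
    "d0_px": ("grouping", "d0_px"),
    "ratio_min": ("artifact", "ratio_min"),
    "roi_margin_factor": ("artifact", "roi_margin_factor"),
    "cyto_method": ("artifact", "cyto_method"),
    "method": (None, "method"),
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a config from a flat mapping; unknown keys are rejected."""
    unknown = set(data) - set(_CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sections: dict[str, dict] = {"segmentation": {}, "grouping": {}, "artifact": {}}
    top: dict = {}
    for key, value in data.items():
        section, name = _CONFIG_KEYS[key]
        if section is None:
            top[name] = value
        else:
            sections[section][name] = value
    try:
        return PipelineConfig(
            segmentation=SegmentationParams(**sections["segmentation"]),
            grouping=GroupingParams(**sections["grouping"]),
            artifact=ArtifactParams(**sections["artifact"]),
            **top,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file (flat keys; unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def config_to_dict(config: PipelineConfig) -> dict:
    out = {}
    for key, (section, name) in _CONFIG_KEYS.items():
        holder = config if section is None else getattr(config, section)
        out[key] = getattr(holder, name)
    return out


@dataclass
class PipelineResult:
    detections: list[NucleusDetection]
    intermediates: dict[str, np.ndarray]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(name, exc) from exc
            log.info("stage %s: %.1f ms", name, 1e3 * (time.perf_counter() - t0))
            return out
        return wrapper
    return deco


def run_pipeline(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    debug_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full nucleus-detection pipeline on one RGB image."""
    config = config or PipelineConfig()
    seg = config.segmentation
    intermediates: dict[str, np.ndarray] = {"01_captured": np.asarray(img)}

    if config.method == "bg":
        diff = _stage("bg_difference")(bg_difference)(img)
        binary = _stage("binarize")(binarize)(diff, seg)
        intermediates["02_bg_difference"] = diff
        intermediates["03_binarization"] = binary
    else:
        binary = _stage("sab_segment")(segment_nucleus_sab)(
            img, seg.min_nucleus_area_px, seg.connectivity
        )
        intermediates["03_binarization"] = binary

    labeled = _stage("label_regions")(label_regions)(binary, seg.connectivity)
    filtered = _stage("size_filter")(size_filter)(labeled, seg.min_nucleus_area_px)
    intermediates["04_segmented_nuclei"] = (filtered.labels > 0).astype(np.uint8)
    intermediates["05_labeled_regions"] = filtered.labels

    raw_dets = _stage("locate_nuclei")(locate_nuclei)(filtered, config.grouping)

    detections: list[NucleusDetection] = []
    thresholds = (
        _stage("global_thresholds")(global_channel_thresholds)(img)
        if raw_dets else None
    )
    for det in raw_dets:
        nucleus_mask = np.isin(filtered.labels, det.member_labels)
        roi = expand_roi(det.bbox, filtered.shape, config.artifact.roi_margin_factor)
        cyto = _stage("segment_cytoplasm")(segment_cytoplasm)(
            img, nucleus_mask, roi, config.artifact, thresholds=thresholds
        )
        flag, ratio = is_artifact(cyto.cyto_area_px, det.area_px, config.artifact)
        detections.append(
            NucleusDetection(
                x_l=det.x_l, x_r=det.x_r, y_t=det.y_t, y_b=det.y_b,
                x_c=det.x_c, y_c=det.y_c, w=det.w, h=det.h,
                area_px=det.area_px, n_lobes=det.n_lobes,
                is_artifact=flag, cyto_nucleus_ratio=ratio,
                member_labels=det.member_labels,
            )
        )

    if debug_dir is not None:
        _write_debug(intermediates, Path(debug_dir))
    return PipelineResult(detections=detections, intermediates=intermediates)


def _write_debug(intermediates: dict[str, np.ndarray], debug_dir: Path) -> None:
    import imageio.v3 as iio

    from .image_io import write_mask

    debug_dir.mkdir(parents=True, exist_ok=True)
    for name in DEBUG_STAGES:
        if name not in intermediates:
            continue
        arr = intermediates[name]
        path = debug_dir / f"{name}.png"
        if arr.ndim == 3:
            iio.imwrite(path, arr)
        elif name == "02_bg_difference":
            iio.imwrite(path, arr)
        elif name == "05_labeled_regions":
            write_mask(arr.astype(np.int32), path)
        else:
            write_mask(arr.astype(np.uint8), path)


@dataclass
class BatchResult:
    per_image: dict[str, list[NucleusDetection]]
    n_images_ok: int
    n_images_failed: int

    @property
    def total_non_artifact(self) -> int:
        return sum(
            sum(1 for d in dets if not d.is_artifact)
            for dets in self.per_image.values()
        )


def run_batch(
    paths: list[str | Path],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> BatchResult:
    """Run the pipeline over many images (lexicographic path order).

    Unreadable images are logged and skipped; the caller decides what a
    fully failed batch means (the CLI exits nonzero).
    """
    from .image_io import read_image, write_detections

    config = config or PipelineConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    per_image: dict[str, list[NucleusDetection]] = {}
    failed = 0
    for path in sorted(Path(p) for p in paths):
        try:
            img = read_image(path)
            result = run_pipeline(img, config)
        except Exception as exc:  # noqa: BLE001 - batch robustness
            log.error("skipping %s: %s", path, exc)
            failed += 1
            continue
        per_image[str(path)] = result.detections
        if out_dir is not None:
            write_detections(result.detections, out_dir / f"{path.stem}_dets.csv")
    return BatchResult(
        per_image=per_image,
        n_images_ok=len(per_image),
        n_images_failed=failed,
    )
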