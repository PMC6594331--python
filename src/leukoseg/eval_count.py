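"""Detection scoring and differential-count reporting.

Detection-level accuracy follows the counting use case: a detection matches
a planted leukocyte when its reported center falls inside the truth bounding
box, matched one-to-one.  Accuracy percentages are reported to one decimal
with exact half-up rounding in integer arithmetic (the rule most consistent
with published per-type accuracy tables computed from integer counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .grouping import NucleusDetection
from .smearsim import LEUKOCYTE_TYPES, SceneTruth


@dataclass(frozen=True)
class MatchResult:
    """One-to-one detection/truth matching outcome."""

    true_positives: int
    false_positives: int
    false_negatives: int
    per_object_matches: tuple[tuple[int, int], ...]  # (truth idx, det idx)

    @property
    def n_truth(self) -> int:
        return self.true_positives + self.false_negatives


@dataclass(frozen=True)
class CountReport:
    """Per-type leukocyte counts and percent proportions."""

    counts: dict[str, int]
    proportions: dict[str, float]
    total: int


def match_detections(
    truth: SceneTruth, dets: Sequence[NucleusDetection]
) -> MatchResult:
    """Greedily match non-artifact detections to truth leukocytes.

    Detections are processed in (x_c, y_c) order; each claims the first
    unmatched truth leukocyte whose closed bbox contains its center.  With
    disjoint truth boxes (guaranteed by the simulator) this equals the
    optimal bipartite matching.
    """
    leukocytes = truth.leukocytes
    candidates = [
        (i, d) for i, d in enumerate(dets) if not d.is_artifact
    ]
    candidates.sort(key=lambda item: (item[1].x_c, item[1].y_c, item[0]))

    matched_truth: set[int] = set()
    matches: list[tuple[int, int]] = []
    for det_idx, det in candidates:
        for t_idx, obj in enumerate(leukocytes):
            if t_idx in matched_truth:
                continue
            x_l, x_r, y_t, y_b = obj.bbox
            if x_l <= det.x_c <= x_r and y_t <= det.y_c <= y_b:
                matched_truth.add(t_idx)
                matches.append((t_idx, det_idx))
                break
    tp = len(matches)
    return MatchResult(
        true_positives=tp,
        false_positives=len(candidates) - tp,
        false_negatives=len(leukocytes) - tp,
        per_object_matches=tuple(sorted(matches)),
    )


def accuracy(tp: int, n_truth: int) -> float:
    """Detection accuracy = 100 * tp / n_truth, as a one-decimal percent.

    Rounding is exact half-up on the tenths digit, done in integer
    arithmetic so results never depend on float representation.
    """
    if n_truth < 1:
        raise ValueError("n_truth must be >= 1")
    if not 0 <= tp <= n_truth:
        raise ValueError("tp must be in [0, n_truth]")
    tenths = (2000 * tp + n_truth) // (2 * n_truth)
    return tenths / 10.0


def match_accuracy(match: MatchResult) -> float:
    """Accuracy of a :class:`MatchResult` (requires at least one truth)."""
    return accuracy(match.true_positives, match.n_truth)


def count_report(labels: Sequence[str]) -> CountReport:
    """Differential count: per-type counts and percent proportions.

    Labels must come from the five leukocyte types.  For a 100-label input
    the proportions equal the counts numerically.  Empty input yields an
    all-zero report with total 0.
    """
    counts = {t: 0 for t in LEUKOCYTE_TYPES}
    for label in labels:
        if label not in counts:
            raise ValueError(f"unknown leukocyte type {label!r}")
        counts[label] += 1
    total = len(labels)
    if total:
        proportions = {t: 100.0 * c / total for t, c in counts.items()}
    else:
        proportions = {t: 0.0 for t in counts}
    return CountReport(counts=counts, proportions=proportions, total=total)


def pixel_f1(pred_mask, truth_mask) -> float:
    """Per-pixel F1 of a predicted foreground mask against truth.

    Used for the synthetic comparison between the B-G method and the SAB
    baseline, where detection-level accuracy is too coarse.
    """
    import numpy as np

    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    if 2 * tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)
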