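"""Evaluation against ground truth: head counts and feeding-time accuracy.

All accuracies use 100 * (1 - relative absolute error), clamped at 0, so a
perfect estimate scores exactly 100.  Visit-level accuracy matches
estimated to true visits greedily by maximal frame-interval overlap (each
side matched at most once); identities are not required to agree, since
manual labels carry no detector ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .feeding import FeedingVisit
from .tracker import TrackRecord

__all__ = [
    "GroundTruth",
    "EvaluationReport",
    "head_count_accuracy",
    "overall_time_accuracy",
    "per_visit_time_accuracy",
    "mean_duration_per_visit",
    "evaluate_run",
    "count_identity_switches",
]

Interval = Tuple[int, int]


@dataclass(frozen=True)
class GroundTruth:
    """Manual annotations for one clip."""

    true_head_count: int
    true_visits: Dict[int, List[Interval]]

    def __post_init__(self) -> None:
        if self.true_head_count < 0:
            raise ValueError("true_head_count must be >= 0")
        for bird, ivs in self.true_visits.items():
            prev_end = None
            for s, e in sorted(ivs):
                if e < s:
                    raise ValueError(f"bird {bird}: interval ({s}, {e}) has end < start")
                if prev_end is not None and s <= prev_end:
                    raise ValueError(f"bird {bird}: overlapping true visits")
                prev_end = e

    def all_intervals(self) -> List[Interval]:
        return sorted(iv for ivs in self.true_visits.values() for iv in ivs)

    def total_seconds(self, fps: float) -> float:
        # sum integer frame counts first so equal streams compare exactly
        return sum(e - s + 1 for s, e in self.all_intervals()) / fps


@dataclass(frozen=True)
class EvaluationReport:
    head_count_accuracy: float
    overall_time_accuracy: float
    per_visit_time_accuracy: float
    mean_duration_per_visit_s: float
    estimated_head_count: int
    true_head_count: int
    estimated_total_s: float
    true_total_s: float
    n_estimated_visits: int
    n_true_visits: int

    def to_dict(self) -> dict:
        return {
            "head_count_accuracy": self.head_count_accuracy,
            "overall_time_accuracy": self.overall_time_accuracy,
            "per_visit_time_accuracy": self.per_visit_time_accuracy,
            "mean_duration_per_visit_s": self.mean_duration_per_visit_s,
            "estimated_head_count": self.estimated_head_count,
            "true_head_count": self.true_head_count,
            "estimated_total_s": self.estimated_total_s,
            "true_total_s": self.true_total_s,
            "n_estimated_visits": self.n_estimated_visits,
            "n_true_visits": self.n_true_visits,
        }


def _relative_accuracy(estimated: float, truth: float) -> float:
    if truth <= 0:
        raise ValueError("truth must be positive (relative error undefined)")
    return 100.0 * max(0.0, 1.0 - abs(estimated - truth) / truth)


def head_count_accuracy(estimated: int, truth: int) -> float:
    """Percent agreement of distinct-head counts, clamped to [0, 100]."""
    return _relative_accuracy(float(estimated), float(truth))


def overall_time_accuracy(estimated_total_s: float, true_total_s: float) -> float:
    """Percent agreement of total feeding seconds, clamped to [0, 100]."""
    return _relative_accuracy(estimated_total_s, true_total_s)


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def per_visit_time_accuracy(
    est_visits: Sequence[FeedingVisit],
    true_visits: Sequence[Interval],
    fps: float,
) -> float:
    """Mean per-visit duration accuracy over all true visits.

    Estimated visits are matched to true visits greedily by maximal frame
    overlap (ties toward the earlier true start, then the earlier estimated
    start); each visit on either side is matched at most once.  A matched
    pair scores ``100 * max(0, 1 - |est - true| / true)`` on durations in
    seconds; unmatched true visits score 0.
    """
    if not true_visits:
        raise ValueError("per_visit_time_accuracy requires at least one true visit")
    if fps <= 0:
        raise ValueError("fps must be positive")
    true_ivs = sorted(true_visits)
    pairs = []
    for ei, v in enumerate(est_visits):
        for ti, iv in enumerate(true_ivs):
            ov = _overlap((v.start_frame, v.end_frame), iv)
            if ov > 0:
                pairs.append((-ov, iv[0], v.start_frame, ti, ei))
    pairs.sort()
    matched: Dict[int, int] = {}
    used_est: set = set()
    for _negov, _ts, _es, ti, ei in pairs:
        if ti in matched or ei in used_est:
            continue
        matched[ti] = ei
        used_est.add(ei)
    scores = []
    for ti, iv in enumerate(true_ivs):
        if ti in matched:
            true_dur = (iv[1] - iv[0] + 1) / fps
            est_dur = est_visits[matched[ti]].duration_s
            scores.append(100.0 * max(0.0, 1.0 - abs(est_dur - true_dur) / true_dur))
        else:
            scores.append(0.0)
    return float(np.mean(scores))


def mean_duration_per_visit(visits: Sequence[FeedingVisit]) -> float:
    """Arithmetic mean of visit durations in seconds."""
    if not visits:
        raise ValueError("mean_duration_per_visit requires at least one visit")
    return float(np.mean([v.duration_s for v in visits]))


def evaluate_run(
    est_visits: Sequence[FeedingVisit],
    estimated_head_count: int,
    truth: GroundTruth,
    fps: float,
) -> EvaluationReport:
    """Full clip-level report comparing a pipeline run against ground truth."""
    true_ivs = truth.all_intervals()
    # sum integer frame counts first so equal streams compare exactly
    est_total = sum(v.n_frames for v in est_visits) / fps
    true_total = truth.total_seconds(fps)
    return EvaluationReport(
        head_count_accuracy=head_count_accuracy(estimated_head_count, truth.true_head_count),
        overall_time_accuracy=overall_time_accuracy(est_total, true_total),
        per_visit_time_accuracy=per_visit_time_accuracy(est_visits, true_ivs, fps),
        mean_duration_per_visit_s=(mean_duration_per_visit(est_visits) if est_visits else 0.0),
        estimated_head_count=estimated_head_count,
        true_head_count=truth.true_head_count,
        estimated_total_s=est_total,
        true_total_s=true_total,
        n_estimated_visits=len(est_visits),
        n_true_visits=len(true_ivs),
    )


def count_identity_switches(
    records: Sequence[TrackRecord],
    true_centers: np.ndarray,
) -> int:
    """Identity switches of estimated tracks against true trajectories.

    Each observation is attributed to the nearest true bird center in its
    frame; a switch is counted whenever that attribution changes between
    consecutive observations of one track.  ``true_centers`` has shape
    ``(n_birds, n_frames, 2)``.
    """
    switches = 0
    for rec in records:
        prev = None
        for frame, bbox in rec.observations:
            c = bbox.center
            d2 = (true_centers[:, frame, 0] - c.x) ** 2 + (true_centers[:, frame, 1] - c.y) ** 2
            bird = int(np.argmin(d2))
            if prev is not None and bird != prev:
                switches += 1
            prev = bird
    return switches
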