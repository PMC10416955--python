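"""Feeding decision, visit segmentation, and feeding-time computation.

A tracked head is feeding in a frame when its feeding index is positive:
the index is the area of the head box intersected with the circular
feeding area, divided by the area of the circle.  An alternative
``center`` criterion (box centroid inside the circle) is also provided.
Contiguous feeding frames of one track form a visit; frame counts divide
by the frame rate to give seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .geometry import (
    BBox,
    Circle,
    Polygon,
    centroid,
    point_in_circle,
    rect_circle_intersection_area,
)
from .tracker import Detection, TrackerParams, TrackRecord, run_tracker

__all__ = [
    "SceneConfig",
    "FrameFeedingStatus",
    "FeedingVisit",
    "FeedingEstimate",
    "index_feed",
    "frame_status",
    "track_statuses",
    "segment_visits",
    "per_bird_report",
    "estimate_feeding",
]

CRITERIA = ("area", "center")


@dataclass(frozen=True)
class SceneConfig:
    """Static description of one camera scene.

    The feeding area (circle) must lie within the image bounds and inside
    the tracking area (polygon); detections are tracked only while their
    centroid is inside the tracking area.
    """

    feeding_area: Circle
    tracking_area: Polygon
    fps: float = 15.0
    image_width: float = 640.0
    image_height: float = 480.0
    params: TrackerParams = field(default_factory=TrackerParams)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        c = self.feeding_area
        if (c.cx - c.r < 0 or c.cy - c.r < 0
                or c.cx + c.r > self.image_width or c.cy + c.r > self.image_height):
            raise ValueError("feeding_area must lie within the image bounds")
        min_x, min_y, max_x, max_y = self.tracking_area.bounds()
        if min_x < 0 or min_y < 0 or max_x > self.image_width or max_y > self.image_height:
            raise ValueError("tracking_area must lie within the image bounds")
        if not self.tracking_area.contains_circle(c):
            raise ValueError("tracking_area must enclose the feeding_area circle")


@dataclass(frozen=True)
class FrameFeedingStatus:
    frame_index: int
    track_id: int
    index_feed: float
    is_feeding: bool


@dataclass(frozen=True)
class FeedingVisit:
    """One contiguous occupancy of the feeder by one track.

    ``n_frames`` counts only the feeding-flagged frames inside
    ``[start_frame, end_frame]``; bridged interruption frames are excluded.
    """

    track_id: int
    start_frame: int
    end_frame: int
    n_frames: int
    duration_s: float


@dataclass
class FeedingEstimate:
    """Output of the end-to-end pipeline on one detection stream."""

    records: List[TrackRecord]
    statuses: Dict[int, List[FrameFeedingStatus]]
    visits: List[FeedingVisit]

    @property
    def n_tracks(self) -> int:
        return len(self.records)

    @property
    def total_feeding_s(self) -> float:
        return sum(v.duration_s for v in self.visits)


def index_feed(head: BBox, feeding_area: Circle) -> float:
    """Intersection area of the head box with the feeding circle, divided
    by the circle area; always in [0, 1], positive iff they overlap."""
    return rect_circle_intersection_area(head, feeding_area) / feeding_area.area


def _is_feeding(head: BBox, feeding_area: Circle, criterion: str, idx: float) -> bool:
    if criterion == "area":
        return idx > 0.0
    if criterion == "center":
        return point_in_circle(centroid(head), feeding_area)
    raise ValueError(f"unknown feeding criterion {criterion!r}; expected one of {CRITERIA}")


def frame_status(
    assignments: Sequence[Tuple[int, Detection]],
    cfg: SceneConfig,
    criterion: str = "area",
) -> List[FrameFeedingStatus]:
    """Feeding status for every tracked head of a single frame."""
    out = []
    for tid, det in assignments:
        idx = index_feed(det.bbox, cfg.feeding_area)
        out.append(FrameFeedingStatus(det.frame_index, tid,
                                      idx, _is_feeding(det.bbox, cfg.feeding_area, criterion, idx)))
    return out


def track_statuses(
    record: TrackRecord,
    cfg: SceneConfig,
    criterion: str = "area",
) -> List[FrameFeedingStatus]:
    """Feeding status for every observation of one track, in frame order."""
    out = []
    for frame, bbox in record.observations:
        idx = index_feed(bbox, cfg.feeding_area)
        out.append(FrameFeedingStatus(frame, record.track_id,
                                      idx, _is_feeding(bbox, cfg.feeding_area, criterion, idx)))
    return out


def segment_visits(
    statuses: Sequence[FrameFeedingStatus],
    fps: float,
    gap_tolerance: int = 0,
) -> List[FeedingVisit]:
    """Split one track's statuses into maximal feeding visits.

    Interruptions of at most ``gap_tolerance`` frames (non-feeding or
    unobserved) do not split a visit; interruption frames are not counted
    in ``n_frames``.  Statuses must belong to a single track and be sorted
    by strictly increasing frame index.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    visits: List[FeedingVisit] = []
    track_id = None
    prev_frame = None
    start = None
    last_feed = None
    n = 0

    def close() -> None:
        nonlocal start, n
        if start is not None:
            visits.append(FeedingVisit(track_id, start, last_feed, n, n / fps))
        start = None
        n = 0

    for s in statuses:
        if track_id is None:
            track_id = s.track_id
        elif s.track_id != track_id:
            raise ValueError("segment_visits expects statuses of a single track")
        if prev_frame is not None and s.frame_index <= prev_frame:
            raise ValueError("statuses must be sorted by strictly increasing frame index")
        prev_frame = s.frame_index
        if not s.is_feeding:
            continue
        if start is None:
            start = s.frame_index
            n = 1
        elif s.frame_index - last_feed - 1 <= gap_tolerance:
            n += 1
        else:
            close()
            start = s.frame_index
            n = 1
        last_feed = s.frame_index
    close()
    return visits


def per_bird_report(visits: Sequence[FeedingVisit]) -> dict:
    """Per-track visit counts and feeding seconds, plus overall means."""
    per_track: Dict[int, dict] = {}
    for v in sorted(visits, key=lambda v: (v.track_id, v.start_frame)):
        entry = per_track.setdefault(v.track_id, {"n_visits": 0, "total_s": 0.0})
        entry["n_visits"] += 1
        entry["total_s"] += v.duration_s
    for entry in per_track.values():
        entry["mean_s_per_visit"] = entry["total_s"] / entry["n_visits"]
    n_visits = len(visits)
    total_s = sum(v.duration_s for v in visits)
    return {
        "per_track": per_track,
        "overall": {
            "n_visits": n_visits,
            "total_s": total_s,
            "mean_s_per_visit": total_s / n_visits if n_visits else 0.0,
        },
    }


def estimate_feeding(
    detections_by_frame: Sequence[Sequence[Detection]],
    cfg: SceneConfig,
    criterion: str = "area",
    gap_tolerance: int = 0,
) -> FeedingEstimate:
    """Track detections, flag feeding frames, and segment visits.

    ``detections_by_frame[i]`` holds the detections of frame ``i``.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown feeding criterion {criterion!r}; expected one of {CRITERIA}")
    records = run_tracker(detections_by_frame, cfg.params, cfg.tracking_area)
    statuses = {r.track_id: track_statuses(r, cfg, criterion) for r in records}
    visits: List[FeedingVisit] = []
    for r in records:
        visits.extend(segment_visits(statuses[r.track_id], cfg.fps, gap_tolerance))
    return FeedingEstimate(records=records, statuses=statuses, visits=visits)
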