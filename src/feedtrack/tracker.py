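"""Euclidean-distance head tracker.

Detections are associated to existing tracks frame by frame using greedy
nearest-first matching on the distance between bounding-box centroids.  A
detection matches a track only when that distance is strictly below the
match radius (default 20 px); otherwise it spawns a new identifier.  Tracks
survive a bounded number of missed frames (default 10) before removal, and
keep a bounded history of recent observations (default 10 frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .geometry import BBox, Point, Polygon, centroid, euclidean_distance, point_in_polygon

__all__ = [
    "Detection",
    "TrackerParams",
    "Track",
    "TrackerState",
    "TrackRecord",
    "step",
    "run_tracker",
]


@dataclass(frozen=True)
class Detection:
    """One head bounding box observed in one frame."""

    frame_index: int
    bbox: BBox
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class TrackerParams:
    match_radius: float = 20.0
    max_missed: int = 10
    history_length: int = 10
    min_confidence: float = 0.5

    def __post_init__(self) -> None:
        if self.match_radius <= 0:
            raise ValueError("match_radius must be positive")
        if self.max_missed < 1:
            raise ValueError("max_missed must be >= 1")
        if self.history_length < 1:
            raise ValueError("history_length must be >= 1")


@dataclass
class Track:
    """A persistent identifier with a bounded observation history.

    ``history`` holds the most recent ``history_length`` observations as
    ``(frame_index, centroid, bbox)`` tuples with strictly increasing frame
    indices.  ``missed_count`` counts consecutive frames without a match;
    while coasting, the last centroid is held static (no motion model).
    """

    track_id: int
    history: List[Tuple[int, Point, BBox]]
    missed_count: int = 0

    @property
    def last_centroid(self) -> Point:
        return self.history[-1][1]

    @property
    def last_frame(self) -> int:
        return self.history[-1][0]


@dataclass
class TrackerState:
    active_tracks: List[Track] = field(default_factory=list)
    next_id: int = 1
    current_frame: int = -1


@dataclass
class TrackRecord:
    """Full observation sequence of one issued identifier."""

    track_id: int
    observations: List[Tuple[int, BBox]] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.observations[0][0]

    @property
    def last_frame(self) -> int:
        return self.observations[-1][0]


def step(
    state: TrackerState,
    detections: Sequence[Detection],
    params: TrackerParams,
    gate: Optional[Polygon] = None,
) -> Tuple[TrackerState, List[Tuple[int, Detection]]]:
    """Advance the tracker by one frame.

    ``state`` is updated in place and returned together with the per-frame
    ``(track_id, detection)`` assignment, listed in detection input order.
    All detections must carry ``frame_index == state.current_frame + 1``;
    frames are consumed strictly one at a time.

    Detections below ``params.min_confidence`` or with centroid outside the
    ``gate`` polygon are discarded before association.  Among all
    (track, detection) pairs closer than ``params.match_radius``, the
    globally smallest-distance pair is committed repeatedly under a
    one-to-one constraint; ties break toward the lower detection input
    index, then the older track.  Unmatched detections spawn new ids in
    input order; unmatched tracks coast, and are removed once
    ``missed_count`` reaches ``params.max_missed``.
    """
    frame = state.current_frame + 1
    for d in detections:
        if d.frame_index != frame:
            raise ValueError(
                f"detection frame_index {d.frame_index} != expected frame {frame}; "
                "frames must be presented consecutively"
            )

    kept: List[Tuple[int, Detection, Point]] = []
    for i, d in enumerate(detections):
        if d.confidence < params.min_confidence:
            continue
        c = centroid(d.bbox)
        if gate is not None and not point_in_polygon(c, gate):
            continue
        kept.append((i, d, c))

    # candidate (distance, detection input index, track creation order)
    candidates: List[Tuple[float, int, int]] = []
    for ti, track in enumerate(state.active_tracks):
        tc = track.last_centroid
        for ki, (di, _d, c) in enumerate(kept):
            dist = euclidean_distance(tc, c)
            if dist < params.match_radius:
                candidates.append((dist, di, ti))
    candidates.sort()

    det_to_track: dict = {}
    used_tracks: set = set()
    for dist, di, ti in candidates:
        if di in det_to_track or ti in used_tracks:
            continue
        det_to_track[di] = ti
        used_tracks.add(ti)

    assignments: List[Tuple[int, Detection]] = []
    for ki, (di, d, c) in enumerate(kept):
        if di in det_to_track:
            track = state.active_tracks[det_to_track[di]]
            track.history.append((frame, c, d.bbox))
            if len(track.history) > params.history_length:
                del track.history[: len(track.history) - params.history_length]
            track.missed_count = 0
            assignments.append((track.track_id, d))
        else:
            track = Track(track_id=state.next_id, history=[(frame, c, d.bbox)])
            state.next_id += 1
            state.active_tracks.append(track)
            assignments.append((track.track_id, d))

    survivors: List[Track] = []
    for ti, track in enumerate(state.active_tracks):
        if track.last_frame == frame:
            survivors.append(track)
            continue
        track.missed_count += 1
        if track.missed_count < params.max_missed:
            survivors.append(track)
    state.active_tracks = survivors
    state.current_frame = frame
    return state, assignments


def run_tracker(
    detections_by_frame: Sequence[Sequence[Detection]],
    params: TrackerParams,
    gate: Optional[Polygon] = None,
) -> List[TrackRecord]:
    """Run :func:`step` over consecutive frames and collect per-id records.

    ``detections_by_frame[i]`` must hold the detections of frame ``i``.
    Returns one :class:`TrackRecord` per issued identifier, ordered by id;
    deterministic for fixed input.
    """
    state = TrackerState()
    records: dict = {}
    for frame_dets in detections_by_frame:
        _, assignments = step(state, frame_dets, params, gate)
        for tid, det in assignments:
            rec = records.get(tid)
            if rec is None:
                rec = records[tid] = TrackRecord(track_id=tid)
            rec.observations.append((det.frame_index, det.bbox))
    return [records[tid] for tid in sorted(records)]
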