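"""Synthetic flock scenarios: ground-truth head trajectories plus noisy detections.

Each bird follows a four-state behavior model — ``wander`` (bounded random
walk inside the tracking polygon, kept clear of the feeder), ``approach``
(biased walk toward an assigned slot on the feeder rim), ``feed`` (head
held overlapping the circle with small jitter), and ``leave`` (biased walk
away from the feeder).  True feeding intervals are read off the generated
geometry; detections are the true boxes corrupted by centroid jitter,
missed detections, and uniform false positives.  All randomness flows from
one seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import BBox, Circle, Point, Polygon, point_in_circle, point_in_polygon, rect_circle_intersection_area
from .feeding import SceneConfig
from .tracker import Detection, TrackerParams

__all__ = ["SimParams", "Scenario", "default_scene", "simulate", "write_scenario"]

_WANDER, _APPROACH, _FEED, _LEAVE = range(4)
# Birds that are not actively feeding keep this far off the feeder rim; the
# clearance exceeds the default head-box half-diagonal, so a head outside the
# clearance ring can never overlap the circle and true visits cannot flicker.
_FEEDER_CLEARANCE = 25.0
_STAGING_CLEARANCE = 40.0  # approach corridor entry point, outside the ring
_LEAVE_CLEARANCE = 30.0


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic scenario generator.

    Motion defaults keep per-frame head displacement well below the 20-px
    match radius at 15 fps, and the minimum pairwise separation above twice
    the match radius, so a noiseless stream is trivially trackable.
    """

    n_birds: int = 5
    n_frames: int = 900
    seed: int = 0
    # motion
    step_scale: float = 4.0          # wander step std per axis, px/frame
    max_step: float = 12.0           # hard cap on any per-frame displacement
    approach_speed: float = 8.0      # px/frame while approaching/leaving
    feed_jitter: float = 1.0         # head jitter std while feeding, px
    min_separation: float = 45.0     # enforced pairwise head-center distance
    # head geometry
    head_w: float = 28.0
    head_h: float = 28.0
    head_size_jitter: float = 2.0    # per-bird size offset std, px
    # behavior transition probabilities (per frame)
    p_start_feeding: float = 0.01    # wander -> approach
    p_stop_feeding: float = 0.01     # feed -> leave
    # detector noise
    sigma: float = 0.0               # centroid jitter std, px
    p_miss: float = 0.0              # per-detection miss probability
    fp_rate: float = 0.0             # Poisson false positives per frame
    conf_range: Tuple[float, float] = (0.85, 1.0)
    fp_conf_range: Tuple[float, float] = (0.3, 0.8)

    def __post_init__(self) -> None:
        if self.n_birds < 0:
            raise ValueError("n_birds must be >= 0")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        for name in ("p_start_feeding", "p_stop_feeding", "p_miss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma < 0 or self.fp_rate < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class Scenario:
    """Ground truth plus the noisy detection stream derived from it."""

    true_tracks: List[List[BBox]]                 # [bird][frame]
    true_centers: np.ndarray                      # (n_birds, n_frames, 2)
    true_visits: Dict[int, List[Tuple[int, int]]]  # bird -> [(start, end)]
    detections_by_frame: List[List[Detection]]
    config: SceneConfig
    n_false_positives: int = 0
    criterion: str = "area"

    @property
    def n_birds(self) -> int:
        return len(self.true_tracks)

    @property
    def n_frames(self) -> int:
        return self.true_centers.shape[1] if self.n_birds else 0

    def all_true_intervals(self) -> List[Tuple[int, int]]:
        """True visits of all birds, flattened and sorted by start frame."""
        out = [iv for ivs in self.true_visits.values() for iv in ivs]
        return sorted(out)


def default_scene(fps: float = 15.0, params: Optional[TrackerParams] = None) -> SceneConfig:
    """A 640x480 scene with a centered 60-px feeder pan."""
    return SceneConfig(
        feeding_area=Circle(320.0, 240.0, 60.0),
        tracking_area=Polygon([(10.0, 10.0), (630.0, 10.0), (630.0, 470.0), (10.0, 470.0)]),
        fps=fps,
        image_width=640.0,
        image_height=480.0,
        params=params or TrackerParams(),
    )


def _feeding_flag(box: BBox, circle: Circle, criterion: str) -> bool:
    if criterion == "center":
        return point_in_circle(box.center, circle)
    return rect_circle_intersection_area(box, circle) > 0.0


def _runs(flags: Sequence[bool]) -> List[Tuple[int, int]]:
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


class _Flock:
    """Mutable per-frame state of the behavior simulation."""

    def __init__(self, p: SimParams, scene: SceneConfig, rng: np.random.Generator):
        self.p = p
        self.scene = scene
        self.rng = rng
        self.circle = scene.feeding_area
        self.poly = scene.tracking_area
        n = p.n_birds
        self.states = [_WANDER] * n
        # one slot per bird on the feeder rim keeps feeding birds separated
        self.angles = [2.0 * math.pi * i / max(n, 1) for i in range(n)]
        angles = self.angles
        self.slots = np.array(
            [[self.circle.cx + self.circle.r * math.cos(a),
              self.circle.cy + self.circle.r * math.sin(a)] for a in angles]
        ).reshape(n, 2)
        # staging points sit on the same angular corridor, outside the
        # clearance ring; the final approach is radial, so two birds on
        # distinct corridors can never come within the separation distance
        stage_r = self.circle.r + _STAGING_CLEARANCE
        self.stagings = np.array(
            [[self.circle.cx + stage_r * math.cos(a),
              self.circle.cy + stage_r * math.sin(a)] for a in angles]
        ).reshape(n, 2)
        self.staged = [False] * n
        self.pos = np.zeros((n, 2))
        for i in range(n):
            self.pos[i] = self._sample_start(i)

    def _ok(self, i: int, xy: np.ndarray, keep_clear: bool) -> bool:
        if not point_in_polygon(Point(xy[0], xy[1]), self.poly):
            return False
        if keep_clear:
            d = math.hypot(xy[0] - self.circle.cx, xy[1] - self.circle.cy)
            if d < self.circle.r + _FEEDER_CLEARANCE:
                return False
        for j in range(self.p.n_birds):
            if j == i:
                continue
            if math.hypot(xy[0] - self.pos[j, 0], xy[1] - self.pos[j, 1]) < self.p.min_separation:
                return False
        return True

    def _sample_start(self, i: int) -> np.ndarray:
        min_x, min_y, max_x, max_y = self.poly.bounds()
        for _ in range(10_000):
            xy = self.rng.uniform((min_x, min_y), (max_x, max_y))
            if self._ok(i, xy, keep_clear=True):
                return xy
        raise RuntimeError("could not place birds: tracking area too crowded")

    def _capped(self, vel: np.ndarray) -> np.ndarray:
        norm = math.hypot(vel[0], vel[1])
        if norm > self.p.max_step:
            vel = vel * (self.p.max_step / norm)
        return vel

    def _try_move(self, i: int, vel: np.ndarray, keep_clear: bool) -> bool:
        xy = self.pos[i] + self._capped(vel)
        if self._ok(i, xy, keep_clear):
            self.pos[i] = xy
            return True
        return False

    def advance(self) -> None:
        p, rng = self.p, self.rng
        for i in range(p.n_birds):
            state = self.states[i]
            if state == _WANDER:
                if rng.random() < p.p_start_feeding:
                    self.states[i] = _APPROACH
                    self.staged[i] = False
                else:
                    self._try_move(i, rng.normal(0.0, p.step_scale, 2), keep_clear=True)
            if self.states[i] == _APPROACH:
                if not self.staged[i]:
                    # phase 1: spiral along the clearance ring toward the
                    # staging point; a straight path could cut through the
                    # ring (or another bird) and stall there forever
                    to_stage = self.stagings[i] - self.pos[i]
                    if math.hypot(to_stage[0], to_stage[1]) < 3.0:
                        self.staged[i] = True
                    else:
                        cx, cy = self.circle.cx, self.circle.cy
                        rel_x = self.pos[i, 0] - cx
                        rel_y = self.pos[i, 1] - cy
                        rcur = max(math.hypot(rel_x, rel_y), 1.0)
                        theta = math.atan2(rel_y, rel_x)
                        dtheta = (self.angles[i] - theta + math.pi) % (2.0 * math.pi) - math.pi
                        radial_speed = 0.7 * p.approach_speed
                        max_ang = radial_speed / rcur
                        new_theta = theta + max(-max_ang, min(max_ang, dtheta))
                        stage_r = self.circle.r + _STAGING_CLEARANCE
                        new_r = rcur + max(-radial_speed, min(radial_speed, stage_r - rcur))
                        cand = np.array([cx + new_r * math.cos(new_theta),
                                         cy + new_r * math.sin(new_theta)])
                        moved = self._try_move(i, cand - self.pos[i], keep_clear=True)
                        if not moved and rng.random() < 0.1:
                            self.states[i] = _WANDER  # blocked; retry later
                        elif math.hypot(*(self.stagings[i] - self.pos[i])) < 3.0:
                            self.staged[i] = True
                if self.staged[i]:
                    # phase 2: deterministic radial descent to the rim slot,
                    # so the box-circle overlap grows monotonically
                    to_slot = self.slots[i] - self.pos[i]
                    dist = math.hypot(to_slot[0], to_slot[1])
                    if dist < 2.0:
                        self.states[i] = _FEED
                    else:
                        speed = min(p.approach_speed, dist)
                        self._try_move(i, to_slot * (speed / dist), keep_clear=False)
                        if math.hypot(*(self.slots[i] - self.pos[i])) < 2.0:
                            self.states[i] = _FEED
            elif self.states[i] == _FEED:
                if rng.random() < p.p_stop_feeding:
                    self.states[i] = _LEAVE
                else:
                    target = self.slots[i] + rng.normal(0.0, p.feed_jitter, 2)
                    self._try_move(i, target - self.pos[i], keep_clear=False)
            elif self.states[i] == _LEAVE:
                away = self.pos[i] - np.array([self.circle.cx, self.circle.cy])
                dist = math.hypot(away[0], away[1])
                if dist > self.circle.r + _LEAVE_CLEARANCE:
                    self.states[i] = _WANDER
                    self.staged[i] = False
                else:
                    away = away / dist if dist > 0 else np.array([1.0, 0.0])
                    self._try_move(i, away * p.approach_speed, keep_clear=False)


def simulate(p: SimParams, scene: Optional[SceneConfig] = None,
             criterion: str = "area") -> Scenario:
    """Generate a reproducible scenario for the given parameters and scene."""
    scene = scene or default_scene()
    rng = np.random.default_rng(p.seed)
    n, T = p.n_birds, p.n_frames

    sizes = np.maximum(
        np.column_stack([
            p.head_w + rng.normal(0.0, p.head_size_jitter, n if n else 0),
            p.head_h + rng.normal(0.0, p.head_size_jitter, n if n else 0),
        ]).reshape(n, 2),
        5.0,
    )

    centers = np.zeros((n, T, 2))
    if n and T:
        flock = _Flock(p, scene, rng)
        for t in range(T):
            if t > 0:
                flock.advance()
            centers[:, t] = flock.pos

    true_tracks: List[List[BBox]] = []
    true_visits: Dict[int, List[Tuple[int, int]]] = {}
    for i in range(n):
        w, h = sizes[i]
        boxes = [BBox(centers[i, t, 0] - w / 2, centers[i, t, 1] - h / 2, w, h)
                 for t in range(T)]
        true_tracks.append(boxes)
        flags = [_feeding_flag(b, scene.feeding_area, criterion) for b in boxes]
        true_visits[i] = _runs(flags)

    min_x, min_y, max_x, max_y = scene.tracking_area.bounds()
    detections_by_frame: List[List[Detection]] = []
    n_fp_total = 0
    for t in range(T):
        frame: List[Detection] = []
        for i in range(n):
            if p.p_miss > 0 and rng.random() < p.p_miss:
                continue
            w, h = sizes[i]
            cx, cy = centers[i, t]
            if p.sigma > 0:
                jit = rng.normal(0.0, p.sigma, 2)
                cx, cy = cx + jit[0], cy + jit[1]
            conf = rng.uniform(*p.conf_range)
            frame.append(Detection(t, BBox(cx - w / 2, cy - h / 2, w, h), conf))
        n_fp = int(rng.poisson(p.fp_rate)) if p.fp_rate > 0 else 0
        for _ in range(n_fp):
            for _attempt in range(1000):
                xy = rng.uniform((min_x, min_y), (max_x, max_y))
                if point_in_polygon(Point(xy[0], xy[1]), scene.tracking_area):
                    break
            fw = max(5.0, p.head_w + rng.normal(0.0, 4.0))
            fh = max(5.0, p.head_h + rng.normal(0.0, 4.0))
            conf = rng.uniform(*p.fp_conf_range)
            frame.append(Detection(t, BBox(xy[0] - fw / 2, xy[1] - fh / 2, fw, fh), conf))
            n_fp_total += 1
        detections_by_frame.append(frame)

    return Scenario(
        true_tracks=true_tracks,
        true_centers=centers,
        true_visits=true_visits,
        detections_by_frame=detections_by_frame,
        config=scene,
        n_false_positives=n_fp_total,
        criterion=criterion,
    )


def write_scenario(s: Scenario, directory) -> Dict[str, Path]:
    """Write detections (MOT CSV), true visits (CSV), head count, and scene YAML.

    Returns a mapping of logical name to written path; all files round-trip
    through the readers in :mod:`feedtrack.io`.
    """
    from . import io as ft_io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": directory / "detections.csv",
        "truth_visits": directory / "truth_visits.csv",
        "head_count": directory / "head_count.txt",
        "scene": directory / "scene.yaml",
    }
    ft_io.write_detections(s.detections_by_frame, paths["detections"])
    ft_io.write_truth_visits(s.true_visits, paths["truth_visits"])
    observed = sum(1 for boxes in s.true_tracks if boxes)
    paths["head_count"].write_text(f"{observed}\n")
    ft_io.write_config(ft_io.RunConfig(scene=s.config, criterion=s.criterion), paths["scene"])
    return paths
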