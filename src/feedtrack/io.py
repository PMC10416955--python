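"""File formats: detections (MOT CSV / YOLO txt), visits, configs, reports.

Detection interchange uses the MOT-Challenge detection dialect::

    frame,id,x,y,w,h,conf,-1,-1,-1

with 1-based frame numbers in the file; internal frame indexing is 0-based
and the conversion happens only at this boundary.  Floats are written with
six decimal places, so writer/reader pairs round-trip losslessly at that
precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .feeding import FeedingVisit, SceneConfig
from .geometry import BBox, Circle, Polygon
from .tracker import Detection, TrackerParams, TrackRecord

__all__ = [
    "RunConfig",
    "read_detections",
    "write_detections",
    "read_visits",
    "write_visits",
    "read_truth_visits",
    "write_truth_visits",
    "read_head_count",
    "load_config",
    "write_config",
    "write_tracks",
    "write_json",
]

_FLOAT_FMT = "{:.6f}"


@dataclass(frozen=True)
class RunConfig:
    """Scene plus run options resolved from a YAML config file."""

    scene: SceneConfig
    criterion: str = "area"
    gap_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in ("area", "center"):
            raise ValueError(f"criterion must be 'area' or 'center', got {self.criterion!r}")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")


def _fmt(v: float) -> str:
    return _FLOAT_FMT.format(v)


# ---------------------------------------------------------------------------
# detections


def _parse_mot(path: Path) -> Dict[int, List[Detection]]:
    frames: Dict[int, List[Detection]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 comma-separated fields, got {len(row)}")
            try:
                frame = int(float(row[0]))
                x, y, w, h = (float(v) for v in row[2:6])
                conf = float(row[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed detection row: {exc}") from exc
            if frame < 1:
                raise ValueError(f"{path}:{lineno}: MOT frame numbers are 1-based, got {frame}")
            if w <= 0 or h <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive box extent w={w}, h={h}")
            fi = frame - 1
            frames.setdefault(fi, []).append(Detection(fi, BBox(x, y, w, h), conf))
    return frames


def _parse_yolo_dir(path: Path, image_size: Tuple[float, float]) -> Dict[int, List[Detection]]:
    img_w, img_h = image_size
    frames: Dict[int, List[Detection]] = {}
    txt_files = sorted(path.glob("*.txt"))
    if not txt_files:
        raise ValueError(f"{path}: no per-frame .txt files found")
    for f in txt_files:
        try:
            fi = int(f.stem.split("_")[-1])
        except ValueError as exc:
            raise ValueError(f"{f}: cannot parse frame index from file name") from exc
        dets: List[Detection] = []
        for lineno, line in enumerate(f.read_text().splitlines(), start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (5, 6):
                raise ValueError(f"{f}:{lineno}: expected 'class cx cy w h [conf]'")
            try:
                cx, cy, wn, hn = (float(v) for v in parts[1:5])
                conf = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{f}:{lineno}: malformed row: {exc}") from exc
            w, h = wn * img_w, hn * img_h
            if w <= 0 or h <= 0:
                raise ValueError(f"{f}:{lineno}: non-positive box extent")
            dets.append(Detection(fi, BBox(cx * img_w - w / 2, cy * img_h - h / 2, w, h), conf))
        frames[fi] = dets
    return frames


def read_detections(
    path,
    dialect: str = "mot",
    image_size: Optional[Tuple[float, float]] = None,
    n_frames: Optional[int] = None,
) -> List[List[Detection]]:
    """Read a detection stream into frame-indexed lists (0-based).

    ``dialect`` is ``mot`` (single CSV, 1-based frames) or ``yolo_txt`` (a
    directory of per-frame files named by 0-based frame index, rows
    ``class cx cy w h [conf]`` normalized to ``image_size``).  Frames absent
    from the file yield empty lists; ``n_frames`` extends/validates the
    stream length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "mot":
        frames = _parse_mot(path)
    elif dialect == "yolo_txt":
        if image_size is None:
            raise ValueError("yolo_txt dialect requires image_size to denormalize")
        frames = _parse_yolo_dir(path, image_size)
    else:
        raise ValueError(f"unknown detection dialect {dialect!r}")
    length = (max(frames) + 1) if frames else 0
    if n_frames is not None:
        if length > n_frames:
            raise ValueError(f"{path}: contains frame {length - 1} beyond n_frames={n_frames}")
        length = n_frames
    return [frames.get(i, []) for i in range(length)]


def write_detections(detections_by_frame: Sequence[Sequence[Detection]], path) -> None:
    """Write detections in the MOT CSV dialect (frames 1-based in-file)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for fi, dets in enumerate(detections_by_frame):
            for d in dets:
                b = d.bbox
                writer.writerow([fi + 1, -1, _fmt(b.x), _fmt(b.y), _fmt(b.w), _fmt(b.h),
                                 _fmt(d.confidence), -1, -1, -1])


def write_tracks(records: Sequence[TrackRecord], path) -> None:
    """Write tracked boxes as MOT rows with resolved ids."""
    path = Path(path)
    rows = []
    for rec in records:
        for frame, b in rec.observations:
            rows.append((frame + 1, rec.track_id, b))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for frame, tid, b in rows:
            writer.writerow([frame, tid, _fmt(b.x), _fmt(b.y), _fmt(b.w), _fmt(b.h),
                             _fmt(1.0), -1, -1, -1])


# ---------------------------------------------------------------------------
# visits


def write_visits(visits: Sequence[FeedingVisit], path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["track_id", "start_frame", "end_frame", "n_frames", "duration_s"])
        for v in sorted(visits, key=lambda v: (v.start_frame, v.track_id)):
            writer.writerow([v.track_id, v.start_frame, v.end_frame, v.n_frames,
                             _fmt(v.duration_s)])


def read_visits(path) -> List[FeedingVisit]:
    path = Path(path)
    visits: List[FeedingVisit] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                visits.append(FeedingVisit(
                    track_id=int(row["track_id"]),
                    start_frame=int(row["start_frame"]),
                    end_frame=int(row["end_frame"]),
                    n_frames=int(row["n_frames"]),
                    duration_s=float(row["duration_s"]),
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed visit row: {exc}") from exc
    return visits


def write_truth_visits(true_visits: Dict[int, List[Tuple[int, int]]], path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bird_id", "start_frame", "end_frame"])
        for bird in sorted(true_visits):
            for s, e in sorted(true_visits[bird]):
                writer.writerow([bird, s, e])


def read_truth_visits(path) -> Dict[int, List[Tuple[int, int]]]:
    path = Path(path)
    out: Dict[int, List[Tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                bird = int(row["bird_id"])
                s, e = int(row["start_frame"]), int(row["end_frame"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed ground-truth row: {exc}") from exc
            out.setdefault(bird, []).append((s, e))
    for ivs in out.values():
        ivs.sort()
    return out


def read_head_count(path) -> int:
    text = Path(path).read_text().strip()
    try:
        return int(text)
    except ValueError as exc:
        raise ValueError(f"{path}: expected a single integer head count") from exc


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> RunConfig:
    """Load and validate a scene/run YAML config, applying defaults.

    Defaults: fps 15, image 640x480, match_radius 20, max_missed 10,
    history_length 10, min_confidence 0.5, criterion 'area',
    gap_tolerance 0.  ``feeding_area`` and ``tracking_area`` are required.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    if "feeding_area" not in raw:
        raise ValueError(f"{path}: missing required key 'feeding_area'")
    if "tracking_area" not in raw:
        raise ValueError(f"{path}: missing required key 'tracking_area'")
    fa = raw["feeding_area"]
    try:
        circle = Circle(float(fa["cx"]), float(fa["cy"]), float(fa["r"]))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: feeding_area must map cx, cy, r") from exc
    try:
        poly = Polygon([(float(v[0]), float(v[1])) for v in raw["tracking_area"]])
    except (TypeError, IndexError) as exc:
        raise ValueError(f"{path}: tracking_area must be a list of [x, y] vertices") from exc
    tr = raw.get("tracker", {}) or {}
    params = TrackerParams(
        match_radius=float(tr.get("match_radius", 20.0)),
        max_missed=int(tr.get("max_missed", 10)),
        history_length=int(tr.get("history_length", 10)),
        min_confidence=float(tr.get("min_confidence", 0.5)),
    )
    scene = SceneConfig(
        feeding_area=circle,
        tracking_area=poly,
        fps=float(raw.get("fps", 15.0)),
        image_width=float(raw.get("image_width", 640.0)),
        image_height=float(raw.get("image_height", 480.0)),
        params=params,
    )
    return RunConfig(
        scene=scene,
        criterion=str(raw.get("criterion", "area")),
        gap_tolerance=int(raw.get("gap_tolerance", 0)),
    )


def write_config(cfg: RunConfig, path) -> None:
    scene = cfg.scene
    doc = {
        "fps": scene.fps,
        "image_width": scene.image_width,
        "image_height": scene.image_height,
        "feeding_area": {"cx": scene.feeding_area.cx, "cy": scene.feeding_area.cy,
                         "r": scene.feeding_area.r},
        "tracking_area": [[p.x, p.y] for p in scene.tracking_area.vertices],
        "tracker": {
            "match_radius": scene.params.match_radius,
            "max_missed": scene.params.max_missed,
            "history_length": scene.params.history_length,
            "min_confidence": scene.params.min_confidence,
        },
        "criterion": cfg.criterion,
        "gap_tolerance": cfg.gap_tolerance,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# reports


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_json(obj: dict, path) -> None:
    """Deterministic JSON: sorted keys, floats rounded to 6 decimals."""
    Path(path).write_text(json.dumps(_round_floats(obj), sort_keys=True, indent=2) + "\n")
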