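# feedtrack

Individual feeding-time estimation from per-frame head detections, for
top-down views of a circular feeder pan. The pipeline is detector-agnostic:
any detector that can emit per-frame bounding boxes (MOT-Challenge CSV or
YOLO-format text) can feed it.

Components:

- **geometry** — exact rectangle–circle intersection area (closed form, no
  sampling), point-in-circle/polygon membership, centroids and distances.
- **tracker** — Euclidean-distance centroid tracking: a detection keeps the
  nearest track's identifier when their centroids are less than 20 px apart
  (greedy nearest-first, one-to-one), otherwise it gets a fresh id; tracks
  keep a 10-frame observation history and expire after 10 missed frames.
- **feeding** — per-frame feeding index: area of the head box intersected
  with the circular feeding area, divided by the circle area; a positive
  index flags a feeding frame (a `center` criterion — box centroid inside
  the circle — is also available). Contiguous feeding frames form visits;
  frame counts divide by the frame rate (default 15 fps) to give seconds.
- **simulate** — synthetic flock scenarios: a four-state behavior model
  (wander / approach / feed / leave) generates true head trajectories and
  feeding intervals, observed through a configurable noisy detector
  (centroid jitter, missed detections, false positives).
- **evaluate** — head-count accuracy, overall feeding-time accuracy, and
  per-visit feeding-time accuracy (greedy interval-overlap matching),
  each as 100·(1 − relative absolute error) clamped at 0.
- **io / cli** — MOT CSV and YOLO txt readers, YAML scene configs, visit
  CSV and JSON report writers, and a `feedtrack` command.

## CLI

Generate a synthetic scenario, run the pipeline against it, and score it:

```sh
feedtrack simulate --out scn --seed 1 --n-birds 5 --n-frames 900 \
    --sigma 2 --p-miss 0.05 --fp-rate 0.1
feedtrack run --config scn/scene.yaml --detections scn/detections.csv \
    --out results --truth-dir scn --gap-tolerance 5
cat results/report.json
```

Individual stages are also exposed: `feedtrack track` (ids only),
`feedtrack feed` (visits + summary), `feedtrack evaluate` (score an
existing visits CSV). Run any subcommand with `--help` for flags.

A scene config is a small YAML file; only the regions are required,
everything else defaults (fps 15, 20 px match radius, 10-frame expiry and
history, 0.5 confidence cutoff, `area` criterion, gap tolerance 0):

```yaml
feeding_area: {cx: 320, cy: 240, r: 60}
tracking_area: [[10, 10], [630, 10], [630, 470], [10, 470]]
```

To plug in a live detector, emit one MOT CSV row per detection
(`frame,-1,x,y,w,h,conf,-1,-1,-1`, frames 1-based) or one YOLO txt file
per frame (`class cx cy w h [conf]`, normalized; file stem ends in the
0-based frame index) and point `--detections` at it.

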