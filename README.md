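# msfit

Computational core of a Kinect-style Pilates exergame for balance
telerehabilitation: 25-joint skeleton-stream processing, gesture-correctness
scoring against reference templates, a gamification engine (coins, city
itinerary, missions, calibration gating), session-use and adherence metrics,
and descriptive statistics for 5-point usability questionnaires. Everything is
exercisable on synthetic motion data — no sensor hardware or downloads needed.

## What it does

- **`msfit.skeleton`** — types and plain-text I/O for time-stamped streams of
  25 named 3D joints (meters, nominal 30 Hz), frame-rate estimation, and
  sensor-placement checks (0.5–4.5 m capture range, 2–3 m recommended band).
- **`msfit.preprocessing`** — causal third-order Butterworth low-pass filtering
  (5 Hz cutoff, bilinear design; zero-phase variant behind a flag) and linear
  resampling.
- **`msfit.kinematics`** — 3D interior joint angles per frame plus angular
  velocity/acceleration from timestamp-aware finite differences.
- **`msfit.scoring`** — gesture correctness: ROM-normalized mean absolute angle
  deviation against a per-joint reference trajectory, weighted across scored
  joints; an execution is *correct* when the error is strictly below 5%.
  Repetition segmentation at angle minima, linear or DTW time alignment, and a
  full stream→scores session pipeline.
- **`msfit.catalog`** — built-in catalog of 14 Pilates exercises
  (breathing/posture/balance; sitting/standing/kneeling) and difficulty-scaled
  per-city protocols.
- **`msfit.game`** — coins per correct repetition, linear city itinerary with
  unlock costs, predicate-based missions (built-in *Methodic*: 2 sessions/day
  for 5 consecutive days), and stillness/posture/range-gated calibration.
- **`msfit.sessions`** — session records, ISO-week use reports, and the
  ≥150 min/week adherence check.
- **`msfit.synthetic`** — articulated-skeleton generator driven by sinusoidal
  joint angles with controllable amplitude scale, phase jitter, and position
  noise; fully seeded, with analytic ground truth for every stage.
- **`msfit.usability`** — Likert questionnaire statistics (mean and n−1 SD,
  half-up 2-decimal rounding) with the 9×8 usability study score matrix as a
  packaged fixture.

## CLI

```bash
msfit simulate --exercise one_leg_circle_1 --reps 5 --scale 1.1 --seed 42 --out stream.csv
msfit validate stream.csv
msfit score stream.csv --exercise one_leg_circle_1
msfit kinematics stream.csv --joint hip_left --out kin.csv
msfit catalog list
msfit play --stream stream.csv --state state.yaml --exercise one_leg_circle_1
msfit report --log sessions.csv --state state.yaml
msfit usability                      # packaged fixture
msfit usability --in responses.csv   # your own data
```

## Skeleton stream format

One frame per line: timestamp in seconds followed by 75 coordinates (25 joints
× x,y,z in the fixed joint order), whitespace- or comma-separated, with a
`#msfit-skeleton v1 fs=<Hz>` header. A CSV variant with named columns
`t,<Joint>_x,<Joint>_y,<Joint>_z` is also accepted; format is auto-detected.
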