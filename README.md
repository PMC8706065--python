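# vorx

Objective compliance scoring for metronome-paced gaze-stabilization
(VORx1) exercises: given a head-angle time series, the library measures
how fast the patient actually turned their head, classifies every head
turn as slow / correct / fast against the prescribed tempo, scores gaze
fixation, and awards reward coins. It also contains a landmark-based
head-pose estimator with rotation-error metrics, a camera-vs-IMU
validation harness (cross-correlation alignment, peak matching, interpeak
and frequency errors, percent-correct comparison), and a synthetic-trial
simulator so everything is exercisable without recorded data.

## Conventions

* One metronome beat = one head turn to one extreme; a full oscillation
  (peak-to-peak) spans two beats, so the ideal peak-to-peak interval is
  `120 / goal_bpm` seconds.
* Angles in degrees, times in seconds, everywhere (files and APIs).
* Head-angle CSV files have the header `time_s,angle_deg` plus a JSON
  sidecar (`<file>.csv.json`) with plane/source/config metadata.

## Modules

| module | contents |
|---|---|
| `vorx.signal_sim` | synthetic trials (phase-modulated sinusoid with tempo drift, frame jitter, amplitude decay, noise, DC offset), paired camera/IMU trials with injected lag, 2D landmark projections, gaze label sequences |
| `vorx.compliance` | time-aware smoothing, prominence/zero-crossing-filtered extrema detection with a 4 deg minimum height, interval-to-bpm conversion, +/-15 bpm compliance classification, gaze percentage, reward coins |
| `vorx.pose` | orthographic-Procrustes pose from named 2D landmarks; per-axis absolute Euler error, pooled MSE, quaternion geodesic |
| `vorx.validation` | series alignment (cross-correlation + DC compensation), one-to-one peak matching with dropped peaks, interpeak/frequency error metrics, paired-trial reports, confusion-matrix accuracy/precision/recall/F1 |
| `vorx.session_io` | symptom/difficulty/session records, CSV + JSON I/O, schema-validated session reports, the CLI |

## CLI

```sh
vorx simulate --goal-bpm 120 --duration 30 --seed 7 --out trial.csv
vorx simulate-pair --goal-bpm 120 --lag 0.2 --seed 7 \
    --out-camera cam.csv --out-reference imu.csv
vorx analyze --series trial.csv --goal-bpm 120 --delta 15 --min-peak 4 --out report.json
vorx validate --camera cam.csv --reference imu.csv --goal-bpm 120 --out table.json
vorx pose --landmarks landmarks.csv            # CSV header: name,x,y
vorx metrics --tn 2002 --fp 72 --fn 107 --tp 951
vorx report --series trial.csv --gaze-percent 95 --goal-bpm 120 --out session.json
```

Exit codes: 0 on success, 2 on input/validation failure. All commands are
deterministic given the same inputs and `--seed`.

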