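# digikit

A hardware-independent engine for digitizing EEG electrode positions with
6-DOF tracked devices (e.g. consumer VR controllers), plus the evaluation
pipeline to score digitizations against a reference. Everything runs on
replayed or synthetic pose streams — no device I/O, no GUI.

Components (all lengths in millimeters):

- **geometry** — rigid transforms (4×4, det +1 enforced to 1e-9), points,
  endpoint offsets; JSONL pose-stream reader/writer with lossless float
  round-trip.
- **calibration** — pivot calibration of the stylus tip: constrained
  minimization of the spread of implied tip positions over N poses sharing a
  fixed physical tip, cross-checked against a closed-form linear pivot
  solution; quality metric = max deviation from the mean tip (mm).
- **acquisition** — trigger handling with 0.5-s trailing averaging, a
  1.0-s / 1-mm stability gate against post-movement error, per-sample
  head-tracker compensation (1–2 trackers) and tracker-slip mismatch
  detection.
- **montage / session** — `.sfp`, `.elc`, `.csv` montage dialects (fiducial
  rows auto-routed), repeated-fiducial averaging with spread warnings,
  measurement ordering (fiducials → electrodes → head shape), lossless JSON
  session persistence, ASCII STL/OFF mesh validation.
- **alignment** — label-matched rigid (Kabsch) alignment by fiducials or by
  electrodes, per-electrode Euclidean errors, RMSE/max aggregation,
  rejection flags, reference-selection rule, Welch's two-tailed t-test.
- **simulator** — synthetic ground truth: quasi-uniform electrode layouts on
  an ellipsoidal head (128-channel layouts hit 18–25 mm neighbor spacing),
  piecewise-rigid head motion, tracker mounts with optional mid-session
  slip, Gaussian translation jitter and decaying post-movement transients.

## CLI

```sh
digikit simulate --config scenario.yaml --out-stream stream.jsonl --out-truth truth.json
digikit calibrate --poses poses.json --bound-mm 200 --out calibration.json
digikit digitize  --replay stream.jsonl --montage cap.sfp --endpoint calibration.json \
                  --trackers tracker1,tracker2 --out session.json
digikit align     --test session.json --ref reference.json --mode electrodes --out result.json
digikit evaluate  --sessions 'sessions/*.json' --reference-rule first-fewest-rejections \
                  --report report.csv
```

Each command writes a `<output>.params.json` record (parameters + version)
sufficient to reproduce the run. Exit codes: 0 ok, 2 usage, 3 missing file,
4 domain error, 5 malformed input.

A scenario YAML mirrors `ScenarioConfig` (electrode count, head semi-axes,
endpoint truth, jitter sigma, transient amplitude/decay, head-motion
waypoints, tracker count/slip, seed); see
`digikit.simulator.ScenarioConfig`.

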