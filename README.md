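# chairkit

A toolkit for a sensor-instrumented office chair: sitting-posture
classification from three seat load cells, and single-lead ECG processing
with beat-level outlier rejection.  Everything is testable at desk scale
through synthetic generators with ground truth.

## What it does

* **`chairkit.chairio`** — session CSV I/O (load-cell block + ECG block at
  their native rates), chair geometry, YAML configuration, CLI.
* **`chairkit.loadcell`** — cleaning of over-capacity readings, 1-s
  non-overlapping moving-average downsampling, center-of-mass (CM) features
  in the seat plane, pushbutton bout splitting.
* **`chairkit.posture`** — k-NN / nearest-centroid / SVM / Gaussian-mixture
  posture classifiers on (CMx, CMy) features; stratified 5-fold CV grid
  search; macro precision/recall/F1 + confusion matrices; seat-plane
  decision maps; transition-period label frequencies.
* **`chairkit.ecg`** — zero-phase FIR band-pass (order 150, 3–45 Hz),
  Hamilton-style adaptive-threshold R-peak detection (implemented from
  scratch), beat segmentation, heart rate, R amplitude, SNR / cosine
  similarity against a reference lead, and detection performance/accuracy.
* **`chairkit.beat_outliers`** — DBSCAN (from scratch, cosine distance),
  DMEAN (adaptive distance-to-template thresholds), and NCCC (greedy
  admission by average normalized cross-correlation) beat outlier detectors.
* **`chairkit.synthgen`** — synthetic posture sessions (per-class Gaussian
  CM clusters from a packaged statistics fixture, weight-conserving
  inversion to cell loads, sensor jitter, over-capacity spikes, pushbutton
  markers) and synthetic ECG (Gaussian-bump beats with known R indices,
  optional broadband artifact bursts).

## CLI

All subcommands accept `--config` (YAML overriding defaults), `--seed`, and
`--out` (a directory receiving a JSON report plus CSV/PNG artifacts):

```sh
chairkit simulate-posture --seed 1 --out out/sp
chairkit simulate-ecg     --seed 1 --burst-rate 3 --out out/se
chairkit posture-train    --seed 1 --family knn --k 1000 --out out/pt
chairkit posture-eval     --seed 2 --model out/pt/model.pkl --out out/pe
chairkit posture-map      --seed 1 --model out/pt/model.pkl --out out/pm
chairkit ecg-process      --seed 1 --session out/se/session.csv --outlier-method dbscan --out out/ep
chairkit ecg-compare      --seed 1 --session out/se/session.csv --outlier-method dbscan --out out/ec
```

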