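# sensorprune

Clustering-based redundancy reduction for wearable pressure-sensor layouts
(e.g. sensor strips inside a prosthetic socket). Given a multi-sensor
pressure recording, the pipeline

1. **cleans and frames** the recording (clamp to the device range, slice
   into fixed-length windows),
2. **detects redundancy**: clusters the sensors of every frame with a
   from-scratch Self-Organizing Map and takes the most common partition
   across frames as the redundancy-detection model (with a K-means
   cross-check),
3. **reduces sensor density**: inside each cluster, exhaustively scores
   every k-subset by the Pearson correlation between the subset centroid
   and the full-cluster centroid, averaged over frames, and keeps the best,
4. **validates** the pruned layout: Jensen-Shannon divergence (base-2, so
   bounded in [0, 1]) between the pooled pressure histograms of each
   cluster and its kept subset, the exhaustive minimum JSD over all
   same-size subsets, and the relative mean-pressure deviation.

A seeded synthetic gait simulator (`sensorprune.synthetic_gait`) generates
recordings with known redundancy-group structure for testing and demos:
10 sensors, 100 Hz, 30 s, ~0.9 gait cycles/s, saturating at 64 kPa.

## CLI

```sh
# generate a synthetic two-group recording (CSV + sidecar JSON)
sensorprune simulate --out rec.csv --seed 1

# build the consensus redundancy-detection model
sensorprune detect rec.csv --frame-length 500 --seed 1 --out model.json

# choose the sensors to keep (global k, or one k per cluster: --k 1,2)
sensorprune select rec.csv --model model.json --k 2 --out selection.json

# validate the pruned layout (JSD + mean pressure; optional histogram PNGs)
sensorprune validate rec.csv --model model.json --selection selection.json \
    --out validation.json --plot-dir plots/

# or everything in one go
sensorprune run rec.csv --out-dir out/ --k 2 --seed 1
```

All randomness is seeded; identical inputs and seeds give byte-identical
JSON outputs. Exit codes: 0 success, 2 configuration error, 3 data error.
Use `-v` / `-vv` before the subcommand for INFO / DEBUG logging.

Input format: CSV with a header row of unique sensor labels and one row per
time sample (values in kPa). An optional sidecar `<stem>.json` supplies
`sampling_rate` (default 100 Hz) and `reading_range` (default `[0, 64]`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: enumeration counts,
framing counts, analytic metric values, brute-force oracle equivalence for
K-means / subset selection / minimum JSD, end-to-end parameter recovery on
the synthetic fixture, and degenerate-input (saturated sensor) handling.

## Layout

- `src/sensorprune/io_framing.py` — recording I/O, cleaning, framing
- `src/sensorprune/synthetic_gait.py` — seeded gait-like simulator
- `src/sensorprune/clustering.py` — SOM and K-means, partitions
- `src/sensorprune/consensus.py` — modal partition across frames
- `src/sensorprune/selection.py` — PCC-based exhaustive subset choice
- `src/sensorprune/validation.py` — histograms, JSD, mean-pressure checks
- `src/sensorprune/cli.py` — subcommands and pipeline orchestration
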