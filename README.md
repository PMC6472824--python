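# bumptraj

Simulation and analysis of periodic neural population dynamics during
rhythmic tapping. The package generates *moving-bump* population activity
(units activating sequentially within each produced interval, repeating
every cycle), projects it into a low-dimensional state space with a single
shared transform, and quantifies the periodic trajectory geometry — radius,
variability and linear speed as a function of tapping tempo — alongside
demixed decomposition, Poisson surprise-index activation-period detection,
SVM tempo decoding with population ablation, and time-delay-network tap
decoding.

## Layout

| module | contents |
| --- | --- |
| `bumptraj.simulate` | moving-bump population simulator (expanding / static regimes), tapping-behavior generator with Weber-law variability, reactive (SRTT-like) control, Poisson spike sampling |
| `bumptraj.tables` | `EventTable` / `SpikeTable` with TSV + JSON-sidecar round trips |
| `bumptraj.binning` | tap-anchored time normalization, UTND (50 bins/segment) and TIND (~20-ms bins) frames, per-neuron max-rate normalization, behavior metrics |
| `bumptraj.geometry` | shared-coefficient projection (`Y = P(X - mean)`), segment radius / variability / speed, sinusoid fits, percentile splits, anchor-point distances, cross-tempo distance profiles |
| `bumptraj.dpca` | marginalized averages and per-parameter reduced-rank encoder/decoder pairs |
| `bumptraj.activation` | Poisson surprise index, greedy burst detection, moving-bump summaries |
| `bumptraj.decoding` | second-layer segment clouds + linear SVM, loading-magnitude ablation, 20-delay / 10-hidden-unit tap decoder (threshold 0.12, 60-ms window) |
| `bumptraj.pipeline` | stage orchestration, YAML config, seeded determinism |

## CLI

```bash
bumptraj simulate --regime expanding --intervals 450,550,650,850,1000 \
    --reps 5 --seed 1 --out runs/sim
bumptraj trajectory --regime expanding --seed 1 --out runs/geom
bumptraj dpca --bins 30 --components 5 --seed 1 --out runs/dpca
bumptraj activations --si-threshold 4.6 --min-spikes 3 --seed 1 --out runs/act
bumptraj decode-interval --repeats 10 --folds 5 --seed 1 --out runs/svm
bumptraj decode-taps --threshold 0.12 --window-ms 60 --seed 1 --out runs/taps
bumptraj run --out runs/full --seed 1          # whole pipeline
```

`bumptraj run` accepts `--config FILE` (YAML, schema = `pipeline.RunConfig`)
and writes per-stage TSV/JSON artifacts plus a `report.json` with
regression tables and timings; outputs are byte-identical for a fixed
config and seed.

## Simulation regimes

* **expanding** — neuron count (108/120/130/170/182) and activation
  duration (197/205/213/233/257 ms) grow with the target interval
  (450/550/650/850/1000 ms); additional units for longer intervals are
  inserted at intermediate positions of the bump.
* **static** — temporal-scaling null: 130 neurons and a constant duty
  cycle (213 ms at 650 ms, stretched proportionally), i.e. the same
  pattern traversed at tempo-dependent speed.

All counts, durations, recruitment width, insertion range, noise level and
seeds are exposed on `simulate.SimulationConfig`.
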