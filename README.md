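# treeaemc

Nondestructive moisture-content (MC) estimation for living tree trunks from
acoustic-emission (AE) waveforms.

Trunk water status is a core variable of tree physiology and forest water
relations, but the standard ways of measuring it (oven drying, resistance
probes) are destructive or laborious. An alternative is acoustic: excite the
trunk periodically with a small vibration motor, record the elastic waves on
the bark with a piezo sensor, and learn the mapping from waveform
characteristics to MC. Wetter wood damps the ring-down faster, shifts the
dominant modes, and couples energy differently — the information is in the
signal, but buried in a nonstationary multi-mode waveform.

`treeaemc` implements that diagnosis chain end to end, plus a synthetic AE
generator with a known MC → signal law so every stage can be validated
against ground truth without field hardware:

1. **ACMD** (`treeaemc.acmd`) — adaptive chirp mode decomposition. The
   signal is modelled as `y(t) = Σᵢ Aᵢ(t) cos(2π∫fᵢ(τ)dτ + φᵢ)`; each
   component is demodulated against a trial frequency f̃(t) into slowly
   varying operators m(t), n(t) by minimizing
   `‖Ωm‖² + ‖Ωn‖² + λ‖y − Gᵢ Bᵢ‖²` (Ω a second-difference matrix, Gᵢ the
   cos/sin kernel at f̃), then f̃ is refined from the residual phase drift
   `arctan(n/m)`. Modes are extracted recursively from the residual.
2. **AE features** (`treeaemc.ae_features`) — threshold/HDT hit detection
   with the standard hit parameters (amplitude, rise time, duration, ring
   count, energy) and fixed-length per-record feature vectors from the
   decomposed modes.
3. **IGWO** (`treeaemc.optimizer`) — grey wolf optimizer improved by three
   joint strategies: Hénon-map population initialization, elite
   opposition-based ("reverse") learning, and a firefly-style perturbation
   with greedy acceptance. Ablation variants and the four standard
   benchmarks (sphere, Rosenbrock, Schwefel, Rastrigin) are included.
4. **GBT** (`treeaemc.gbt`) — second-order gradient-boosted regression
   trees written from scratch: squared-error grad/Hessian, optimal leaf
   weight `ξ* = −G/(H+η)`, structure score
   `J = −½ Σ G²/(H+η) + γT`, exact greedy split search.
5. **Pipeline** (`treeaemc.pipeline`) — decompose → featurize → 8:2 split →
   IGWO-tuned boosting (k-fold CV RMSE objective) → RMSE/MAE/MAPE/R²
   report, plus a decomposition-vs-raw-features ablation.

## Worked example

```bash
python examples/simulate_and_decompose.py
```

```
record: 800 samples at 2000 Hz, mc = 80.0%
true mode frequencies: ['160.0 Hz', '460.0 Hz', '860.0 Hz']

ACMD extracted 3 modes (residual energy ratio 0.011):
  mode 0: median IF   160.0 Hz, peak envelope 0.685, energy 58.1
  mode 1: median IF   460.0 Hz, peak envelope 0.413, energy 21.1
  mode 2: median IF   860.0 Hz, peak envelope 0.234, energy 7.0
```

The simulator placed three ring-down modes at 200/500/900 Hz shifted down
by 0.5 Hz per %MC (so 160/460/860 Hz at 80% MC); ACMD recovers each
carrier to a fraction of a hertz and the three narrowband modes explain
99% of the record energy (the remainder is the injected noise).

```bash
python examples/tune_and_diagnose.py
```

```
records: 30  (train 24, test 6)
cross-validated RMSE at optimum: 7.91 %MC
held-out test metrics:
  rmse         2.999
  mae          1.965
  mape         2.916
  r2           0.988
  accuracy    97.084
```

RMSE/MAE are in percentage points of moisture content; accuracy is
defined as 100 − MAPE (MC is itself a percentage). `examples/
optimizer_benchmark.py` prints the strategy-ablation table on the
standard test functions.

A thin CLI wraps the same functions:

```bash
treeaemc simulate --seed 1 --mc 80 --out rec.csv
treeaemc decompose rec.csv --out modes/
treeaemc benchmark --function sphere --runs 10 --out table.csv
```

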