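# gaitnet

EEG brain-network analysis and decoding of lower-limb gait motor imagery.

Motor-imagery therapy can partially restore lower-limb function after a
stroke, and decoding *which* gait a person is imagining — a normal walking
gait (MCI) versus a post-stroke hemiplegic gait (IEG) — is a prerequisite for
closed-loop imagery training. Discriminating the two conditions is less about
how strongly individual areas activate than about how cortical areas
*coordinate*, so the decisive features here come from directed brain
networks rather than channel-wise power alone.

`gaitnet` implements the full analysis chain for 32-channel (or smaller)
EEG epochs of imagery trials:

1. **Preprocessing** — baseline-drift correction, zero-phase 8–30 Hz
   elliptic band-pass (plus a 1–45 Hz branch for spectral/ERP analyses),
   ICA removal of ocular and myogenic components, epoching with a
   gross-noise screen.
2. **Time domain** — movement-related cortical potential (MRCP) stacking
   and averaging, per-channel peak amplitude / latency / Hilbert phase,
   numeric scalp-amplitude maps at fixed latencies.
3. **Spectra** — Welch power spectra, absolute band power
   `ABSP_task = POWER_task − POWER_REST`, band powers, and Hilbert–Huang
   time–frequency energy via empirical mode decomposition.
4. **Connectivity** — the core. A multivariate autoregressive (MVAR) model

   ```
   X(t) = Σ_{k=1..p} A(k) X(t−k) + E(t)
   ```

   is fitted by pooled least squares (order `p` chosen by BIC). From the
   spectral transfer matrix `H(f) = A(f)^{-1}` the **full-frequency DTF**

   ```
   F²_ij(f) = |H_ij(f)|² / Σ_f Σ_k |H_ik(f)|²
   ```

   and the **partial coherence** `C_ij(f)` (from minors of the spectral
   matrix `S(f) = H Σ H*`) combine into the **direct DTF**

   ```
   χ²_ij(f) = F²_ij(f) · C²_ij(f),
   ```

   which suppresses influence mediated through third channels. Band-mean
   dDTF, thresholded at 0.2 (after max-normalization), yields the directed
   brain graph.
5. **Graph metrics** — characteristic path length, global efficiency,
   clustering coefficient, local efficiency, and per-node path length.
6. **Decoding & statistics** — five feature families (MRCP peaks, AR-model
   band power, HHT energy, nodal path length, and a CSP-style spatial
   filter over adjacency-space) feed an SVM under stratified
   cross-validation with all fitting confined to training folds; nodal path
   lengths are compared across tasks by repeated-measures ANOVA.

Because comparable public recordings do not exist, the package ships a
first-class synthetic-data module that generates trials from MVAR systems
with *known* directed connectivity, a planted negative ERP near 200 ms,
class-specific band power (alpha-dominant MCI, theta-dominant IEG), baseline
drift and optional blink artifacts — so every stage is validated against
ground truth.

## Worked example

```python
from gaitnet import (MVAR, default_class_specs, simulate_trial_set,
                     graph_metrics)
from gaitnet.preprocess import detrend_epochs, bandpass_epochs

specs = default_class_specs(n_channels=8, order=3, seed=7)
epochs, truth = simulate_trial_set(specs, n_trials_per_class=30, seed=0)

narrow = bandpass_epochs(detrend_epochs(epochs), 8, 30)
result = MVAR.from_epochs(narrow, "MCI").fit(p_max=10)
conn = result.connectivity(band=(8, 30), threshold=0.2)
print(conn.summary())
print(graph_metrics(conn.adjacency).summary())
```

prints

```
Directed connectivity (dDTF)
==================================
channels:          8
frequency grid:    1-45 Hz (45 points)
aggregation band:  8-30 Hz
weight scaling:    max
threshold:         0.2
edges:             13 / 56 possible
Graph metrics
==============================
characteristic path length: 1.6400  (unreachable pairs: 31)
global efficiency:          0.3274
clustering coefficient:     0.5000
local efficiency:           0.5312
```

The MCI condition's trial-pooled MVAR fit yields a directed graph with 13
edges at the 0.2 threshold; its reachable node pairs are on average 1.64
hops apart, and about a third of all ordered pairs communicate efficiently
(global efficiency 0.33). Decoding the two imagery classes from per-trial
networks — nodal path lengths combined with adjacency-space spatial-filter
features, all fitted inside cross-validation folds —

```python
from gaitnet import EpochSet, per_trial_networks, train_eval_svm
from gaitnet.features import features_netattr

keep = [lab != "REST" for lab in narrow.labels]
imagery_only = EpochSet(narrow.data[keep],
                        [l for l in narrow.labels if l != "REST"],
                        narrow.rate, channel_names=narrow.channel_names)
nets = per_trial_networks(imagery_only, p_max=10)
report = train_eval_svm(features_netattr(nets), seed=0,
                        adj_weights=nets.weights)
print(report.summary())
# netattr+adjspace: 100.00% +- 0.00% (5-fold CV, classes ['IEG', 'MCI'])
```

separates the planted 0.2 edge-density difference perfectly at this noise
level; single feature families score lower (see `docs/methods.md`).

## Command line

Each stage is also a subcommand:

```bash
gaitnet simulate  --config cfg.yaml --out run/ --seed 1
gaitnet preprocess --in rec.edf --out run/
gaitnet connect   --in run/epochs_clean --band 8:30 --threshold 0.2 --out run/
gaitnet metrics   --in run/ --directed --out run/
gaitnet decode    --in run/epochs_raw --families netattr,combo --out run/
gaitnet run-all   --config cfg.yaml --out run/ --seed 1
```

`run-all` executes simulate → preprocess → MRCP/spectra → connectivity →
graph metrics → decoding → statistics and writes a manifest with the config
hash, the seed, per-stage timings and every artifact path.

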