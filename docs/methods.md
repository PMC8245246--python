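# Methods

This note documents the models, the numerical choices, and what the
synthetic data can and cannot establish. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The MVAR / dDTF connectivity model

Multichannel EEG `X(t)` (N channels) is modelled as a vector autoregression
`X(t) = Σ_{k=1..p} A(k) X(t−k) + E(t)` with Gaussian innovations of
covariance Σ. Estimation is ordinary least squares on the stacked lag
regression, pooling epochs so that no regressor window straddles a trial
boundary. The innovation covariance is the maximum-likelihood residual
covariance (normalized by the number of regression rows), which is what the
BIC uses:

```
BIC(p) = ln det(Σ̂_p) + ln(n_obs) · N²p / n_obs,
```

minimized over `p = 1..p_max` (ties to the smallest order). On synthetic
order-4 systems with genuine order-4 structure this recovers the true order
essentially always at n = 5000 (the acceptance script reports the rate).

The frequency domain uses `A(f) = I − Σ_k A(k) exp(−i2πfk/rate)` (the
`A(0) = −I` convention), `H(f) = A(f)^{-1}`, and the spectral matrix
`S(f) = H(f) Σ H(f)*`. Three couplings are derived per ordered pair, with
**row = sink, column = source** (entry `[i, j]` is flow `j → i`):

* **ffDTF**: `F²_ij(f) = |H_ij(f)|² / Σ_f Σ_k |H_ik(f)|²`. The denominator
  runs over the *entire* frequency grid, so each row sums to exactly one
  over sources and frequencies — asserted to 1e-6 throughout the tests.
* **Partial coherence**: `C_ij(f) = |M_ij| / sqrt(M_ii M_jj)` with `M_ij`
  the minor of `S(f)` deleting row i / column j. Implementation uses the
  cofactor identity `M_ij = ±det(S)(S^{-1})_ji`, in which `det(S)` cancels:
  `|C_ij| = |(S^{-1})_ji| / sqrt((S^{-1})_ii (S^{-1})_jj)`. The literal
  minor-determinant route is kept as an independent oracle in the tests.
  Magnitudes are clipped to [0, 1].
* **dDTF**: `χ²_ij(f) = F²_ij(f) · C²_ij(f)`. The squaring of C follows the
  defining product form; since `C² ≤ 1`, dDTF never exceeds ffDTF, which is
  exactly its purpose — a mediated path (1→2→3) keeps a sizeable ffDTF on
  the spurious 1→3 pair but a small partial coherence, so the product
  suppresses it.

**Threshold scale.** Because the ffDTF denominator spans the whole grid, a
single band-mean dDTF entry is of order `1/(n_freqs·N)` (≈ 0.003 at 45
frequencies × 8 channels) — a raw threshold of 0.2 would produce empty
graphs for any system. The band-aggregated weight matrix is therefore
normalized by its largest off-diagonal entry before thresholding
(`normalize="max"`, the default), making 0.2 a *relative* cut against the
strongest connection; `normalize="none"` exposes the raw band means (used
for the independence-null check, where the 95th percentile of off-diagonal
weights on uncoupled channels sits near 1e-8).

Frequency grid: 1 Hz spacing, 1–45 Hz. Aggregation band: 8–30 Hz, the
preprocessing passband. Per-trial fits on 3 s epochs can be marginally
unstable (spectral radius just above 1 from sampling noise); they are
shrunk lag-wise (`A(k) → g^k A(k)`, which scales companion eigenvalues by
`g` exactly) to radius 0.99 before evaluating `H(f)`. Trial-pooled class
fits are used for the per-class networks; per-trial fits (at the class-level
BIC order) feed the classification features.

## Graph measures

Distances are BFS hop counts; unreachable pairs are `inf`.

* Characteristic path length: mean of the *finite* off-diagonal distances,
  with the unreachable-pair count reported rather than folded into the mean
  (an empty graph yields NaN plus a full count, never an exception inside
  the pipeline).
* Global efficiency: mean of `1/d_ij` with `1/inf = 0` — the standard
  definition; isolated nodes depress rather than poison it.
* Clustering `cl_i = 2e_i/(k_i(k_i−1))` (degree < 2 ⇒ 0) and local
  efficiency are undirected quantities; the directed dDTF adjacency is
  OR-symmetrized for them. Path length, global efficiency and nodal path
  length run on the directed graph by default; both modes are exposed since
  the choice is genuinely open.
* Nodal path length (outgoing mean distance) is the 32-dimensional network
  feature; nodes reaching nothing are imputed with the trial's largest
  finite nodal value + 1 so feature matrices stay finite.

All measures agree exactly with Floyd–Warshall and brute-force triple
enumeration on random graphs up to N = 16 (and with networkx).

## Preprocessing

Baseline drift correction is a per-channel least-squares linear detrend
(idempotent). The band-pass is a 4th-order elliptic design, 0.5 dB passband
ripple, 40 dB stopband attenuation, applied forward–backward (zero phase;
attenuation effectively doubles). Band set: delta 1–3, theta 4–7, alpha
8–13, beta 14–30, gamma 30–45 Hz; a narrow 14–16 Hz beta row is kept for
the absolute-power summaries. Two branches coexist deliberately: the 8–30 Hz
branch feeds connectivity and decoding, a 1–45 Hz branch feeds spectral and
ERP analyses (theta-band results are unobtainable from an 8–30 Hz signal).

ICA artifact removal decomposes the concatenated epochs (FastICA by
default, extended infomax optional — the contract is flag-and-zero, not the
algorithm). A component is *ocular* when its time course correlates ≥ 0.8
with the < 5 Hz low-passed signal of a frontal channel: blinks live below
5 Hz, and correlating against the raw frontal channel instead would flag any
genuine frontal neural component on small montages. A component is
*myogenic* when ≥ 70 % of its spectral power lies above 30 Hz. Flagged
components are zeroed and the data reconstructed; zero flags reconstructs
the input to numerical precision.

## Spectra and the Hilbert–Huang branch

PSDs are Welch estimates (1 s Hann segments, 50 % overlap) averaged over
trials; `ABSP_task = PSD_task − PSD_REST` element-wise. Band power is the
trapezoidal integral over the band.

EMD sifts with cubic-spline envelopes through local extrema, mirror-extending
10 % of the signal at each end against end-swings. A sift stops when the
normalized successive difference falls below 0.05; decomposition stops at 10
IMFs or when the residual has fewer than three interior extrema (monotone or
constant residuals produce no IMFs). The residual is *defined* as input minus
the IMF sum, so reconstruction is exact by construction and asserted to 1e-8.
HHT energy is `0.5 · Σ_IMFs Σ_t |hilbert(imf)|²`: the ½ converts squared
narrowband envelopes to signal energy (for a narrowband component
`Σ env² = 2 Σ x²`), making the feature comparable to `Σ x²(t)` — verified to
15 % on band-limited noise. Inside feature extraction, trials are zero-phase
decimated (default ×4; EEG content here lies below 45 Hz) before sifting.

## Decoding

Feature families per trial (d = channel count unless noted): signed MRCP
extremum amplitude in 100–400 ms (instantaneous Hilbert phase at the peak is
exposed and can be appended, doubling d — peak-only is the default since two
scalars per channel would not be a channel-dimensional feature); Burg AR
(order 8) spectrum integrated over 8–30 Hz; HHT energy; nodal path length;
and a CSP-style adjacency-space projection. The spatial filter symmetrizes
each trial's weight matrix, shifts it above its smallest eigenvalue to
guarantee positive definiteness, trace-normalizes, and solves the
generalized eigenproblem of the two class means; the top/bottom eight
eigenvectors give 16 log-quadratic-form features on a 32-channel montage
(capped at N components on smaller ones). This construction is an
interpretation: the adjacency-space "spatial filter" has no canonical
definition in this setting.

Classification is an RBF-kernel SVM (C = 1, gamma = 1/(d·var)) under
stratified 5-fold CV. Standardization and the spatial filter are fitted
inside each training fold; the leakage guard (shuffled labels with the
filter in the loop staying at chance over 20 seeds) is part of acceptance.
Accuracies are reported as mean ± across-fold standard deviation, in
percent.

The statistics stage compares nodal path lengths of a 15-channel subset
(F3, F4, FC3, FC4, C3, Cz, C4, CP3, CP4, P3, Pz, P4, O1, O2, Oz) across
task pairs by one-way repeated-measures ANOVA over paired trials at
α = 0.05, including the cross-channel cells (channel a under task 1 vs
channel b under task 2) — an unusual grid reproduced deliberately. The
two-condition grid is computed vectorized (F equals the squared paired t);
it matches statsmodels' AnovaRM in the tests, and its type-I rate under a
simulated null calibrates to 0.03–0.07 at α = 0.05 over 1000 reps. Raw
p-values are reported; Holm correction is available as an option.

## Synthetic data: what it emulates, what it does not

Each trial is an MVAR draw (burn-in ≥ max(10p, 100) samples) plus additive
components:

* **ERP**: Gaussian-windowed deflection, σ = 30 ms, default −5 µV at 200 ms
  (MCI) / −4 µV at 210 ms (IEG), spatially weighted toward C3/Cz/C4 (a
  centred bump on unlabeled montages).
* **Oscillation**: unit-RMS band-limited Gaussian noise scaled by
  `band_gain` (default 2.0) — alpha for MCI, theta for IEG, none for REST.
* **Drift**: per-trial quadratic polynomial with random coefficients
  (amplitude 2 µV by default).
* **Blink**: 300 ms raised-cosine pulse (60 µV) on the two most frontal
  channels at the configured per-trial rate.

Directed edge sets per condition are drawn once at densities IEG 0.27,
MCI 0.07, REST 0.04 (coupling 0.45): the imagery classes differ in edge
density by 0.2, and the induced characteristic path lengths order
REST > MCI > IEG. Edge coefficients sit at lag 1 and half-strength at the
final lag, so an order-p system genuinely has order-p structure. Trial
timing follows the block paradigm (5 s cross, 2 s cue, 3 s imagery, 5 s
rest; one MCI, one IEG and two epoched rest windows per block, 50 blocks by
default). Sampling is 1000 Hz with a 32-channel extended 10–20 montage by
default; small montages (2–8 channels) are supported for oracle tests, and
the default decoding experiments use 8 channels with 60 trials per class —
sizes at which every stage completes in seconds to minutes on one CPU.

What the generator does **not** emulate: volume conduction / a forward head
model (channels are not linear mixtures of shared sources, which flatters
ICA and CSP relative to real scalp data), between-subject variability,
non-stationarity within a session, and realistic 1/f background beyond what
the MVAR diagonal induces. Passing tests therefore establish that the
estimators recover what was planted under the stated noise model — not
field performance on recorded EEG.

## Defaults worth knowing

| parameter | default | why |
|---|---|---|
| frequency grid | 1–45 Hz, 1 Hz | acquisition low-pass at 45 Hz |
| aggregation band | 8–30 Hz | the connectivity passband |
| dDTF threshold | 0.2 of max off-diagonal weight | see "Threshold scale" |
| BIC p_max | 10 (pipeline), 20 (API) | 3 s epochs support ~10 lags of 8 channels |
| elliptic design | order 4, 0.5 dB / 40 dB | filter family fixed, parameters chosen |
| ICA thresholds | corr 0.8 (EOG band), HF fraction 0.7 | separates planted blinks from clean components |
| SVM | RBF, C = 1, gamma scale, 5-fold | small-sample default |
| ANOVA α | 0.05, raw p | Holm available as a flag |
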