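"""Synthetic gait-imagery EEG with known ground truth.

Every downstream stage (preprocessing, MRCP averaging, spectra, dDTF
networks, decoding) is validated against data generated here, because the
study's recordings have no public accession. Each simulated trial is

    MVAR background  +  ERP deflection  +  band-limited oscillation
    +  polynomial baseline drift  +  (optionally) a stereotyped blink,

with per-class ground truth (directed adjacency of the generating MVAR
system, ERP latency and spatial profile, dominant band) returned alongside
the epochs so recovery can be asserted, not eyeballed.

Class phenomenology emulated (defaults):

* MCI (normal-gait imagery): alpha-dominant oscillation, negative ERP near
  200 ms over sensorimotor channels, sparse directed network.
* IEG (hemiplegic-gait imagery): theta-dominant, negative ERP near 200 ms,
  the densest directed network (its characteristic path length is the
  shortest of the three conditions).
* REST: no ERP, no dominant band, near-empty network.

Trial timing follows the block paradigm: 5 s fixation cross, 2 s cue, 3 s
imagery, 5 s rest, twice per block (once per imagery class), 50 blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import CHANNELS_32, EEGRecording, EpochSet, BANDS
from .mvar import VARProcess, UnstableModelError

__all__ = [
    "TrialTiming",
    "ClassSpec",
    "GroundTruth",
    "make_mvar_system",
    "simulate_recording",
    "simulate_trial_set",
    "simulate_blocks",
    "simulate_session_recording",
    "default_class_specs",
    "default_edge_sets",
    "erp_spatial_weights",
]


@dataclass
class TrialTiming:
    """Block paradigm durations in seconds."""

    cross_s: float = 5.0
    cue_s: float = 2.0
    imagery_s: float = 3.0
    rest_s: float = 5.0
    blocks: int = 50

    def __post_init__(self) -> None:
        for name in ("cross_s", "cue_s", "imagery_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.blocks < 1:
            raise ValueError("blocks must be >= 1")


@dataclass
class ClassSpec:
    """Generating recipe for one task condition.

    ``erp_amplitude`` is in microvolts (negative for the ~200 ms deflection);
    ``band_gain`` scales a unit-RMS band-limited oscillation added on top of
    the MVAR background; ``erp_weights`` optionally overrides the spatial
    profile of the ERP (defaults to a sensorimotor-focused profile).
    """

    label: str
    model: VARProcess
    erp_peak_latency_ms: float = 200.0
    erp_amplitude: float = 0.0
    dominant_band: str = "none"
    band_gain: float = 0.0
    erp_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.band_gain < 0:
            raise ValueError("band_gain must be >= 0")
        if self.dominant_band not in ("theta", "alpha", "beta", "none"):
            raise ValueError(f"unknown band {self.dominant_band!r}")


@dataclass
class GroundTruth:
    """What was planted, per class: for recovery tests."""

    adjacency: dict[str, np.ndarray]
    erp_latency_ms: dict[str, float]
    erp_amplitude: dict[str, float]
    erp_weights: dict[str, np.ndarray]
    dominant_band: dict[str, str]
    seed: int = 0
    extras: dict = field(default_factory=dict)


def true_adjacency(process: VARProcess) -> np.ndarray:
    """Binary directed adjacency of a generating system: adjacency[i, j] = 1
    iff some lag couples source j into sink i (off-diagonal)."""
    adj = (np.abs(process.coeffs) > 1e-12).any(axis=0).astype(int)
    np.fill_diagonal(adj, 0)
    return adj


# ---------------------------------------------------------------------------
# system construction


def make_mvar_system(n_channels: int, order: int,
                     edges: list[tuple[int, int, float]] | None = None,
                     seed: int = 0, target_radius: float = 0.95,
                     max_rescale: int = 25) -> VARProcess:
    """Build a stable MVAR system with a prescribed directed edge set.

    ``edges`` is a list of ``(source, sink, strength)`` with 0-based channel
    indices; off-diagonal coefficients are nonzero exactly on those edges
    (strength at lag 1, strength/2 at the final lag when the order allows,
    so a system of order p genuinely has order-p structure). Diagonal
    lags carry a decaying autoregression with small seeded jitter. If the
    companion spectral radius reaches ``target_radius`` the coefficients are
    shrunk lag-wise (A(k) -> g^k A(k), which scales the eigenvalues by g)
    until stable; an edge list that cannot be stabilized within
    ``max_rescale`` shrinkages is rejected.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    edges = edges or []
    for src, snk, _ in edges:
        if not (0 <= src < n_channels and 0 <= snk < n_channels):
            raise ValueError(f"edge ({src}->{snk}) outside 0..{n_channels - 1}")
        if src == snk:
            raise ValueError("self-edges belong to the diagonal, not the edge list")
    rng = np.random.default_rng(seed)
    coeffs = np.zeros((order, n_channels, n_channels))
    base = np.array([0.45, -0.12, 0.05])  # decaying diagonal AR
    for k in range(order):
        diag = (base[k] if k < len(base) else 0.0) + rng.uniform(
            -0.03, 0.03, n_channels
        )
        coeffs[k][np.diag_indices(n_channels)] = diag
    for src, snk, strength in edges:
        coeffs[0, snk, src] = strength
        if order >= 2:
            coeffs[order - 1, snk, src] = strength / 2.0
    proc = VARProcess(coeffs, np.eye(n_channels))
    for _ in range(max_rescale):
        rad = proc.spectral_radius
        if rad < target_radius:
            return proc
        g = min(0.98 * target_radius / rad, 0.95)
        scale = g ** np.arange(1, order + 1)
        proc = VARProcess(coeffs * scale[:, None, None], np.eye(n_channels))
        coeffs = proc.coeffs
    raise UnstableModelError(
        f"could not stabilize system within {max_rescale} rescalings"
    )


def simulate_recording(model: VARProcess, n_samples: int, rate_hz: float = 1000.0,
                       seed: int = 0, labels: list[str] | None = None) -> EEGRecording:
    """Run the MVAR recursion forward with Gaussian innovations.

    A burn-in of ``max(10 * order, 100)`` samples is generated and discarded
    so the returned series is (approximately) stationary. Unstable models
    are refused.
    """
    if not model.is_stable:
        raise UnstableModelError("refusing to simulate an unstable model")
    if n_samples <= 10 * model.order:
        raise ValueError("n_samples must exceed 10 * order")
    rng = np.random.default_rng(seed)
    n, p = model.n_channels, model.order
    burn = max(10 * p, 100)
    total = n_samples + burn
    chol = np.linalg.cholesky(
        model.noise_cov + 1e-12 * np.eye(n)
    )
    e = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    coeffs = model.coeffs
    for t in range(p, total):
        acc = e[t].copy()
        for k in range(p):
            acc += coeffs[k] @ x[t - k - 1]
        x[t] = acc
    if labels is None:
        labels = [f"ch{i + 1:02d}" for i in range(n)]
    return EEGRecording(x[burn:].T, rate_hz, labels)


# ---------------------------------------------------------------------------
# trial components


def erp_spatial_weights(labels: list[str]) -> np.ndarray:
    """Spatial profile of the planted ERP: concentrated on C3/Cz/C4 when the
    montage names them, otherwise a bump over the middle channels."""
    focus = {"Cz": 1.0, "C3": 0.8, "C4": 0.8, "FC3": 0.4, "FC4": 0.4,
             "FCz": 0.5, "CP3": 0.4, "CP4": 0.4, "CPz": 0.5}
    if any(lab in focus for lab in labels):
        return np.array([focus.get(lab, 0.05) for lab in labels])
    n = len(labels)
    pos = np.arange(n)
    return np.exp(-0.5 * ((pos - (n - 1) / 2) / max(n / 6.0, 1.0)) ** 2)


def _erp_template(n_samples: int, rate_hz: float, latency_ms: float,
                  amplitude: float, sigma_ms: float = 30.0) -> np.ndarray:
    t_ms = np.arange(n_samples) * 1000.0 / rate_hz
    return amplitude * np.exp(-0.5 * ((t_ms - latency_ms) / sigma_ms) ** 2)


def _band_noise(n_samples: int, rate_hz: float, band_name: str,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to the named canonical band."""
    band = BANDS[band_name]
    sos = signal.butter(4, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=rate_hz, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples + 200))[100:-100]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _blink_template(n_samples: int, rate_hz: float, onset_ms: float,
                    amplitude: float = 60.0, width_ms: float = 300.0) -> np.ndarray:
    """Raised-cosine EOG pulse."""
    t_ms = np.arange(n_samples) * 1000.0 / rate_hz
    out = np.zeros(n_samples)
    inside = (t_ms >= onset_ms) & (t_ms <= onset_ms + width_ms)
    phase = (t_ms[inside] - onset_ms) / width_ms
    out[inside] = amplitude * 0.5 * (1 - np.cos(2 * np.pi * phase))
    return out


def _simulate_one_trial(spec: ClassSpec, n_samples: int, rate_hz: float,
                        weights: np.ndarray, drift_amplitude: float,
                        add_blink: bool, rng: np.random.Generator) -> np.ndarray:
    rec = simulate_recording(
        spec.model, n_samples, rate_hz, seed=int(rng.integers(2**31))
    )
    x = rec.data
    n_ch = x.shape[0]
    if spec.erp_amplitude != 0.0:
        erp = _erp_template(n_samples, rate_hz, spec.erp_peak_latency_ms,
                            spec.erp_amplitude)
        x = x + np.outer(weights, erp)
    if spec.band_gain > 0 and spec.dominant_band != "none":
        for ch in range(n_ch):
            x[ch] += spec.band_gain * _band_noise(
                n_samples, rate_hz, spec.dominant_band, rng
            )
    if drift_amplitude > 0:
        tt = np.linspace(-1, 1, n_samples)
        c = rng.uniform(-1, 1, (n_ch, 3)) * drift_amplitude
        x = x + c[:, [0]] + c[:, [1]] * tt + c[:, [2]] * tt**2
    if add_blink:
        onset = rng.uniform(0, max(n_samples * 1000.0 / rate_hz - 320.0, 1.0))
        blink = _blink_template(n_samples, rate_hz, onset)
        for ch in range(min(2, n_ch)):  # two most frontal channels
            x[ch] += blink
    return x


def simulate_trial_set(class_specs: list[ClassSpec],
                       n_trials_per_class: int | dict[str, int],
                       timing: TrialTiming | None = None,
                       rate_hz: float = 1000.0,
                       drift_amplitude: float = 0.0,
                       artifact_rate: float = 0.0,
                       seed: int = 0) -> tuple[EpochSet, GroundTruth]:
    """Generate labelled imagery epochs plus the planted ground truth.

    Each trial spans the imagery window (``timing.imagery_s`` seconds).
    ``n_trials_per_class`` may be a single count or a per-label dict.
    ``artifact_rate`` is the per-trial probability of a frontal blink.
    """
    timing = timing or TrialTiming()
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    n_samples = int(round(timing.imagery_s * rate_hz))
    max_order = max(s.model.order for s in class_specs)
    if n_samples < 10 * max_order:
        raise ValueError("imagery window too short for the model order")
    counts = (
        {s.label: n_trials_per_class for s in class_specs}
        if isinstance(n_trials_per_class, int)
        else dict(n_trials_per_class)
    )
    for lab, c in counts.items():
        if c < 2:
            raise ValueError(f"need >= 2 trials per class (got {c} for {lab})")
    n_ch = class_specs[0].model.n_channels
    labels_mont = CHANNELS_32 if n_ch == 32 else [f"ch{i + 1:02d}" for i in range(n_ch)]
    rng = np.random.default_rng(seed)
    trials, labels = [], []
    weights_by_class = {}
    for spec in class_specs:
        w = spec.erp_weights if spec.erp_weights is not None else erp_spatial_weights(labels_mont)
        weights_by_class[spec.label] = np.asarray(w, dtype=float)
        for _ in range(counts[spec.label]):
            add_blink = bool(rng.random() < artifact_rate)
            trials.append(
                _simulate_one_trial(spec, n_samples, rate_hz,
                                    weights_by_class[spec.label],
                                    drift_amplitude, add_blink, rng)
            )
            labels.append(spec.label)
    # interleave trials so folds/blocks mix classes
    order = np.random.default_rng(seed + 1).permutation(len(trials))
    epochs = EpochSet(
        np.stack([trials[i] for i in order]),
        [labels[i] for i in order],
        rate_hz, t0_ms=0.0, channel_names=labels_mont,
    )
    truth = GroundTruth(
        adjacency={s.label: true_adjacency(s.model) for s in class_specs},
        erp_latency_ms={s.label: s.erp_peak_latency_ms for s in class_specs},
        erp_amplitude={s.label: s.erp_amplitude for s in class_specs},
        erp_weights=weights_by_class,
        dominant_band={s.label: s.dominant_band for s in class_specs},
        seed=seed,
    )
    return epochs, truth


def simulate_blocks(class_specs: list[ClassSpec], timing: TrialTiming | None = None,
                    **kwargs) -> tuple[EpochSet, GroundTruth]:
    """Trial counts implied by the block paradigm: each block contributes one
    MCI trial, one IEG trial and two epoched rest windows."""
    timing = timing or TrialTiming()
    counts: dict[str, int] = {}
    for spec in class_specs:
        counts[spec.label] = (
            2 * timing.blocks if spec.label == "REST" else timing.blocks
        )
    return simulate_trial_set(class_specs, counts, timing, **kwargs)


def simulate_session_recording(class_specs: list[ClassSpec],
                               timing: TrialTiming | None = None,
                               rate_hz: float = 1000.0,
                               seed: int = 0) -> EEGRecording:
    """Continuous block-structured recording with event markers.

    Segments are laid end to end per block (cross, cue, MCI imagery, rest,
    cue, IEG imagery, rest); imagery and rest onsets carry events. Inter-task
    segments are drawn from the REST model.
    """
    timing = timing or TrialTiming()
    by_label = {s.label: s for s in class_specs}
    if "REST" not in by_label:
        raise ValueError("session simulation needs a REST spec")
    rng = np.random.default_rng(seed)
    n_ch = class_specs[0].model.n_channels
    labels_mont = CHANNELS_32 if n_ch == 32 else [f"ch{i + 1:02d}" for i in range(n_ch)]

    def seg(spec: ClassSpec, dur_s: float) -> np.ndarray:
        n = int(round(dur_s * rate_hz))
        w = (spec.erp_weights if spec.erp_weights is not None
             else erp_spatial_weights(labels_mont))
        return _simulate_one_trial(spec, n, rate_hz, np.asarray(w, float),
                                   0.0, False, rng)

    rest_bg = ClassSpec("REST", by_label["REST"].model)  # no ERP during filler
    pieces, events = [], []
    cursor = 0
    for _ in range(timing.blocks):
        plan = [
            (rest_bg, timing.cross_s, None),
            (rest_bg, timing.cue_s, None),
            (by_label["MCI"], timing.imagery_s, "MCI"),
            (by_label["REST"], timing.rest_s, "REST"),
            (rest_bg, timing.cue_s, None),
            (by_label["IEG"], timing.imagery_s, "IEG"),
            (by_label["REST"], timing.rest_s, "REST"),
        ]
        for spec, dur, ev in plan:
            if ev is not None:
                events.append((cursor, ev))
            x = seg(spec, dur)
            pieces.append(x)
            cursor += x.shape[1]
    return EEGRecording(np.concatenate(pieces, axis=1), rate_hz, labels_mont, events)


# ---------------------------------------------------------------------------
# study-condition defaults


def default_edge_sets(n_channels: int = 8, seed: int = 7,
                      coupling: float = 0.45) -> dict[str, list[tuple[int, int, float]]]:
    """Directed edge sets per condition at the study's default densities.

    Densities (fraction of the N(N-1) ordered pairs): IEG 0.27, MCI 0.07,
    REST 0.04 — the imagery classes differ in edge density by 0.2, and the
    induced characteristic path lengths order REST > MCI > IEG.
    """
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n_channels) for j in range(n_channels) if i != j]
    densities = {"IEG": 0.27, "MCI": 0.07, "REST": 0.04}
    out = {}
    for label, dens in densities.items():
        k = max(2, int(round(dens * len(pairs))))
        idx = rng.choice(len(pairs), size=k, replace=False)
        out[label] = [(pairs[i][0], pairs[i][1], coupling) for i in idx]
    return out


def default_class_specs(n_channels: int = 8, order: int = 3,
                        seed: int = 7) -> list[ClassSpec]:
    """Study-condition class recipes: MCI alpha-dominant with a -5 uV ERP at
    200 ms, IEG theta-dominant with a -4 uV ERP at 210 ms, REST flat."""
    edge_sets = default_edge_sets(n_channels, seed=seed)
    specs = []
    recipes = {
        "MCI": dict(erp_peak_latency_ms=200.0, erp_amplitude=-5.0,
                    dominant_band="alpha", band_gain=2.0),
        "IEG": dict(erp_peak_latency_ms=210.0, erp_amplitude=-4.0,
                    dominant_band="theta", band_gain=2.0),
        "REST": dict(erp_amplitude=0.0, dominant_band="none", band_gain=0.0),
    }
    for i, (label, kw) in enumerate(recipes.items()):
        model = make_mvar_system(n_channels, order, edge_sets[label],
                                 seed=seed + 13 * i)
        specs.append(ClassSpec(label, model, **kw))
    return specs
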