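"""Preprocessing: drift correction, elliptic band-pass, ICA artifact removal,
band extraction and epoching.

The pipeline order follows the acquisition-to-analysis convention: baseline
drift correction, 8-30 Hz elliptic band-pass (or the broader 1-45 Hz branch
used for spectral/MRCP analyses), ICA-based removal of ocular and myogenic
components, then epoching around imagery onsets with a gross-noise screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import BandDefinition, EEGRecording, EpochSet


class DecompositionError(RuntimeError):
    """ICA decomposition failed; never silently passed through."""


def correct_baseline_drift(rec: EEGRecording) -> EEGRecording:
    """Remove a per-channel least-squares linear trend (baseline drift)."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel")
    if not np.isfinite(rec.data).all():
        raise ValueError("non-finite samples in recording")
    return rec.copy_with(signal.detrend(rec.data, axis=1, type="linear"))


def detrend_epochs(epochs: EpochSet) -> EpochSet:
    """Per-trial, per-channel linear detrend (drift correction on epochs)."""
    if not np.isfinite(epochs.data).all():
        raise ValueError("non-finite samples in epochs")
    return EpochSet(signal.detrend(epochs.data, axis=2, type="linear"),
                    list(epochs.labels), epochs.rate, epochs.t0_ms,
                    epochs.channel_names)


def elliptic_sos(low_hz: float, high_hz: float, rate: float, order: int = 4,
                 ripple_db: float = 0.5, atten_db: float = 40.0) -> np.ndarray:
    """Design the elliptic band-pass in second-order sections."""
    nyq = rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    return signal.ellip(order, ripple_db, atten_db, [low_hz, high_hz],
                        btype="bandpass", fs=rate, output="sos")


def bandpass_elliptic(rec: EEGRecording, low_hz: float = 8.0, high_hz: float = 30.0,
                      order: int = 4, ripple_db: float = 0.5,
                      atten_db: float = 40.0) -> EEGRecording:
    """Zero-phase elliptic band-pass (forward-backward, so no phase lag)."""
    sos = elliptic_sos(low_hz, high_hz, rec.rate, order, ripple_db, atten_db)
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=1))


def bandpass_epochs(epochs: EpochSet, low_hz: float, high_hz: float,
                    order: int = 4, ripple_db: float = 0.5,
                    atten_db: float = 40.0) -> EpochSet:
    """Zero-phase elliptic band-pass applied per trial."""
    sos = elliptic_sos(low_hz, high_hz, epochs.rate, order, ripple_db, atten_db)
    return EpochSet(signal.sosfiltfilt(sos, epochs.data, axis=2),
                    list(epochs.labels), epochs.rate, epochs.t0_ms,
                    epochs.channel_names)


def extract_band(rec: EEGRecording, band: BandDefinition) -> EEGRecording:
    """Band-pass-restricted copy using the same elliptic design."""
    return bandpass_elliptic(rec, band.low_hz, band.high_hz)


# ---------------------------------------------------------------------------
# ICA artifact suppression


@dataclass
class ICAReport:
    """Which components were flagged and why."""

    n_components: int
    ocular: list[int] = field(default_factory=list)
    myogenic: list[int] = field(default_factory=list)
    frontal_corr: np.ndarray | None = None
    hf_fraction: np.ndarray | None = None

    @property
    def flagged(self) -> list[int]:
        return sorted(set(self.ocular) | set(self.myogenic))


def remove_artifacts_ica(epochs: EpochSet,
                         frontal_labels: tuple[str, ...] = ("Fp1", "Fp2"),
                         corr_threshold: float = 0.8,
                         hf_ratio_threshold: float = 0.7,
                         method: str = "fastica",
                         seed: int = 0) -> tuple[EpochSet, ICAReport]:
    """Decompose concatenated epochs with ICA, zero flagged components,
    reconstruct.

    A component is flagged *ocular* if the absolute correlation of its time
    course with the EOG-band (< 5 Hz low-passed) signal of any frontal
    channel reaches ``corr_threshold`` — blinks live below 5 Hz, so
    broadband neural components that happen to project frontally are not
    mistaken for them — and
    *myogenic* if the fraction of its spectral power above 30 Hz reaches
    ``hf_ratio_threshold``. ``method`` is "fastica" or "infomax"; the
    contract (flag and zero) is identical for both.
    """
    n_ch = epochs.n_channels
    x = epochs.concatenated()  # (ch, T)
    if x.shape[1] <= n_ch:
        raise ValueError("need more time points than channels")
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    try:
        if method == "fastica":
            from sklearn.decomposition import FastICA

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ica = FastICA(n_components=n_ch, whiten="unit-variance",
                              random_state=seed, max_iter=500)
                sources = ica.fit_transform(xc.T).T  # (k, T)
            mixing = ica.mixing_  # (ch, k)
        elif method == "infomax":
            from mne.preprocessing import infomax

            unmixing = infomax(xc.T, random_state=seed, verbose="error")
            sources = unmixing @ xc
            mixing = np.linalg.pinv(unmixing)
        else:
            raise ValueError(f"unknown ICA method {method!r}")
    except (np.linalg.LinAlgError, ValueError) as err:
        if isinstance(err, ValueError) and "unknown ICA method" in str(err):
            raise
        raise DecompositionError(f"ICA failed: {err}") from err
    if not np.isfinite(sources).all() or not np.isfinite(mixing).all():
        raise DecompositionError("ICA produced non-finite components")

    # frontal channels for the ocular rule
    if epochs.channel_names:
        fr_idx = [i for i, lab in enumerate(epochs.channel_names)
                  if lab in frontal_labels]
    else:
        fr_idx = []
    if not fr_idx:
        fr_idx = [0, 1][: n_ch]
    # blinks are < 5 Hz events: correlate against the EOG band only
    lp = signal.butter(4, min(5.0, 0.45 * epochs.rate), btype="lowpass",
                       fs=epochs.rate, output="sos")
    frontal = signal.sosfiltfilt(lp, x[fr_idx], axis=1)

    k = sources.shape[0]
    corr = np.zeros(k)
    for c in range(k):
        s = sources[c]
        if s.std() == 0:
            continue
        cc = [abs(np.corrcoef(s, f)[0, 1]) for f in frontal if f.std() > 0]
        corr[c] = max(cc) if cc else 0.0
    ocular = [c for c in range(k) if corr[c] >= corr_threshold]

    hf = np.zeros(k)
    nper = min(sources.shape[1], int(epochs.rate))
    for c in range(k):
        freqs, psd = signal.welch(sources[c], fs=epochs.rate, nperseg=nper)
        tot = psd.sum()
        hf[c] = psd[freqs > 30.0].sum() / tot if tot > 0 else 0.0
    myogenic = [c for c in range(k) if hf[c] >= hf_ratio_threshold]

    report = ICAReport(k, ocular, myogenic, corr, hf)
    keep = np.array([c not in report.flagged for c in range(k)])
    if report.flagged:
        clean = mixing[:, keep] @ sources[keep] + mean
    else:
        clean = mixing @ sources + mean  # numerically ~ the input
    # concatenated() laid trials end to end along time: invert that layout
    data = np.stack(np.split(clean, epochs.n_trials, axis=1))
    out = EpochSet(data, list(epochs.labels), epochs.rate, epochs.t0_ms,
                   epochs.channel_names)
    return out, report


# ---------------------------------------------------------------------------
# epoching


def epoch(rec: EEGRecording, window_ms: tuple[float, float] = (0.0, 3000.0),
          amplitude_ceiling: float | None = None) -> tuple[EpochSet, int]:
    """Cut one trial per event; screen out grossly noisy trials.

    Trials containing any sample with ``|x| > amplitude_ceiling`` are dropped
    and counted (the returned int). An empty event list yields an empty
    EpochSet, not an error.
    """
    lo = int(round(window_ms[0] * rec.rate / 1000.0))
    hi = int(round(window_ms[1] * rec.rate / 1000.0))
    if hi <= lo:
        raise ValueError("empty epoch window")
    n_samp = hi - lo
    trials, labels = [], []
    dropped = 0
    for idx, lab in rec.events:
        a, b = idx + lo, idx + hi
        if a < 0 or b > rec.n_samples:
            raise ValueError(f"epoch window for event at {idx} outside recording")
        seg = rec.data[:, a:b]
        if amplitude_ceiling is not None and np.abs(seg).max() > amplitude_ceiling:
            dropped += 1
            continue
        trials.append(seg)
        labels.append(lab)
    data = (np.stack(trials) if trials
            else np.empty((0, rec.n_channels, n_samp)))
    return EpochSet(data, labels, rec.rate, t0_ms=window_ms[0],
                    channel_names=list(rec.labels)), dropped
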