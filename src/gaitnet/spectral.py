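"""Power spectra, absolute band power, and Hilbert-Huang time-frequency energy.

Power spectral densities are Welch-averaged periodograms pooled over trials
(1 s Hann segments, 50% overlap by default). The absolute power (ABSP) of a
task is its PSD minus the REST PSD, channel by channel and frequency by
frequency — the paper's normalization for between-subject and
between-electrode power offsets.

The Hilbert-Huang branch decomposes each channel with empirical mode
decomposition (EMD) — iterative sifting with cubic-spline envelopes and
mirror end-extension — and sums the squared instantaneous (Hilbert)
amplitude over intrinsic mode functions and time. A factor 1/2 converts
squared narrowband envelopes to signal energy, so the result is comparable
to sum(x^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .data import BandDefinition, EpochSet


@dataclass
class PowerSpectrum:
    """Per-channel PSD in uV^2/Hz on a common frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    class_label: str | None = None
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


@dataclass
class AbsolutePower:
    """Task-minus-REST PSD difference (may be negative)."""

    freqs: np.ndarray
    delta_power: np.ndarray
    pair: tuple[str, str]


def power_spectrum(epochs: EpochSet, class_label: str | None = None,
                   segment_s: float = 1.0, overlap: float = 0.5) -> PowerSpectrum:
    """Welch PSD averaged over trials and segments, per channel."""
    sub = epochs.select(class_label) if class_label else epochs
    nper = int(round(segment_s * sub.rate))
    if nper > sub.n_samples:
        raise ValueError(
            f"segment ({nper} samples) longer than epoch ({sub.n_samples})"
        )
    freqs, psd = sps.welch(sub.data, fs=sub.rate, nperseg=nper,
                           noverlap=int(round(nper * overlap)),
                           window="hann", axis=2)
    return PowerSpectrum(freqs, psd.mean(axis=0), class_label,
                         {"segment_s": segment_s, "overlap": overlap,
                          "window": "hann", "n_trials": sub.n_trials})


def absolute_power(task_psd: PowerSpectrum, rest_psd: PowerSpectrum) -> AbsolutePower:
    """Element-wise PSD difference: task minus rest."""
    if task_psd.power.shape != rest_psd.power.shape or not np.allclose(
        task_psd.freqs, rest_psd.freqs
    ):
        raise ValueError("PSDs must share frequency grid and channel set")
    return AbsolutePower(task_psd.freqs, task_psd.power - rest_psd.power,
                         (task_psd.class_label or "task",
                          rest_psd.class_label or "REST"))


def band_power(psd: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    """Trapezoidal integral of the PSD over [low_hz, high_hz], per channel."""
    sel = (psd.freqs >= band.low_hz) & (psd.freqs <= band.high_hz)
    if sel.sum() < 2:
        raise ValueError(f"band {band.name} covers <2 grid frequencies")
    return np.trapezoid(psd.power[:, sel], psd.freqs[sel], axis=1)


# ---------------------------------------------------------------------------
# empirical mode decomposition


def _extrema(x: np.ndarray):
    d = np.diff(x)
    maxima = np.flatnonzero((np.hstack([d, -1]) < 0) & (np.hstack([1, d]) > 0))
    minima = np.flatnonzero((np.hstack([d, 1]) > 0) & (np.hstack([-1, d]) < 0))
    return maxima, minima


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of upper/lower cubic-spline envelopes with mirror extension.

    Returns None when there are too few extrema to build envelopes.
    """
    n = len(x)
    next_ = max(n // 10, 2)  # mirror 10% of the length at each end
    left = x[1 : next_ + 1][::-1]
    right = x[-next_ - 1 : -1][::-1]
    ext = np.concatenate([left, x, right])
    idx = np.arange(-len(left), n + len(right))
    maxima, minima = _extrema(ext)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    t = np.arange(n)
    upper = CubicSpline(idx[maxima], ext[maxima])(t)
    lower = CubicSpline(idx[minima], ext[minima])(t)
    return (upper + lower) / 2.0


def emd(x: np.ndarray, max_imfs: int = 10, sift_tol: float = 0.05,
        max_sifts: int = 50):
    """Empirical mode decomposition by sifting.

    A sift iterates ``h <- h - mean(envelopes)`` until the normalized
    successive difference ``sum((h_prev - h)^2) / sum(h_prev^2)`` drops below
    ``sift_tol``. Decomposition stops at ``max_imfs`` or when the residual
    has too few extrema (monotone / constant). The residual is defined as
    input minus the IMF sum, so reconstruction is exact by construction.

    Returns
    -------
    (imfs, residual) : list of ndarray, ndarray
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if len(x) < 16:
        raise ValueError("signal too short for EMD (need >= 16 samples)")
    imfs: list[np.ndarray] = []
    res = x.copy()
    for _ in range(max_imfs):
        # a residual without interior oscillation (monotone, constant) is done;
        # check extrema of the signal itself, not the mirror extension
        n_max, n_min = (len(ix) for ix in _extrema(res))
        if n_max + n_min < 3:
            break
        m = _envelope_mean(res)
        if m is None:
            break
        h = res - m
        for _ in range(max_sifts):
            m = _envelope_mean(h)
            if m is None:
                break
            h_new = h - m
            denom = float(np.sum(h**2))
            if denom == 0:
                h = h_new
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < sift_tol:
                break
        imfs.append(h)
        res = res - h
    residual = x - (np.sum(imfs, axis=0) if imfs else 0.0)
    return imfs, residual


def hht_energy_1d(x: np.ndarray, **emd_kwargs) -> float:
    """Hilbert-Huang energy of one signal: half the squared Hilbert amplitude
    summed over IMFs and time (the residual trend is excluded)."""
    imfs, _ = emd(x, **emd_kwargs)
    if not imfs:
        return 0.0
    total = 0.0
    for imf in imfs:
        total += float(np.sum(np.abs(sps.hilbert(imf)) ** 2))
    return 0.5 * total


def hht_energy(epochs: EpochSet, **emd_kwargs) -> np.ndarray:
    """Per-trial, per-channel HHT energy, shape (n_trials, n_channels)."""
    out = np.empty((epochs.n_trials, epochs.n_channels))
    for ti in range(epochs.n_trials):
        for ch in range(epochs.n_channels):
            out[ti, ch] = hht_energy_1d(epochs.data[ti, ch], **emd_kwargs)
    return out
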