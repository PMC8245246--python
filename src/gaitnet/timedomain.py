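"""Movement-related cortical potentials: stacking, averaging, peak/phase,
and numeric scalp-amplitude maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .data import EpochSet


@dataclass
class MRCPAverage:
    """Trial-averaged potentials for one task condition (channels x samples)."""

    data: np.ndarray
    n_trials: int
    class_label: str
    rate: float
    t0_ms: float = 0.0
    channel_names: list[str] | None = None

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.data.shape[1]) * 1000.0 / self.rate


def average_mrcp(epochs: EpochSet, class_label: str) -> MRCPAverage:
    """Arithmetic mean over all trials of the given class."""
    sub = epochs.select(class_label)  # raises on unknown class
    return MRCPAverage(sub.data.mean(axis=0), sub.n_trials, class_label,
                       epochs.rate, epochs.t0_ms, epochs.channel_names)


def grand_average(avg: MRCPAverage) -> np.ndarray:
    """Mean over channels at each sample (one scalar series)."""
    return avg.data.mean(axis=0)


def mrcp_peak_phase(avg: MRCPAverage,
                    search_window_ms: tuple[float, float] = (100.0, 400.0)):
    """Per-channel peak amplitude, peak latency and instantaneous phase.

    The peak is the extremum of largest magnitude inside the search window
    (ties broken toward the earliest latency); the phase is the angle of the
    analytic signal (Hilbert transform over the whole epoch) at the peak
    sample, in (-pi, pi].

    Returns
    -------
    (peak_amplitude, peak_latency_ms, phase_rad) : three (n_channels,) arrays
    """
    t = avg.times_ms
    sel = np.flatnonzero((t >= search_window_ms[0]) & (t <= search_window_ms[1]))
    if sel.size < 3:
        raise ValueError("search window shorter than 3 samples")
    analytic = hilbert(avg.data, axis=1)
    amps = np.empty(avg.data.shape[0])
    lats = np.empty(avg.data.shape[0])
    phases = np.empty(avg.data.shape[0])
    for ch in range(avg.data.shape[0]):
        seg = avg.data[ch, sel]
        k = int(np.argmax(np.abs(seg)))  # argmax returns the first maximum: earliest tie
        idx = sel[k]
        amps[ch] = avg.data[ch, idx]
        lats[ch] = t[idx]
        ph = float(np.angle(analytic[ch, idx]))
        phases[ch] = ph if ph > -np.pi else np.pi  # fold -pi to +pi
    return amps, lats, phases


def phase_difference(phase_a: np.ndarray, phase_b: np.ndarray) -> np.ndarray:
    """Per-channel wrapped difference of two phase vectors, in (-pi, pi].

    Convenience for comparing conditions; an interpretation, since the peak
    phases of two conditions generally refer to different latencies.
    """
    d = np.mod(phase_a - phase_b + np.pi, 2 * np.pi) - np.pi
    d[d == -np.pi] = np.pi
    return d


def scalp_map(avg: MRCPAverage,
              latencies_ms=(1.0, 100.0, 200.0, 300.0, 400.0, 500.0),
              half_window_ms: float = 10.0) -> np.ndarray:
    """Numeric per-channel amplitude map at fixed latencies.

    Each cell is the mean amplitude in a +-``half_window_ms`` window around
    the latency (single instants are noisy). Shape (n_latencies, n_channels);
    no rendering is performed.
    """
    t = avg.times_ms
    out = np.empty((len(latencies_ms), avg.data.shape[0]))
    for li, lat in enumerate(latencies_ms):
        if lat < t[0] or lat > t[-1]:
            raise ValueError(f"latency {lat} ms outside epoch [{t[0]}, {t[-1]}] ms")
        sel = (t >= lat - half_window_ms) & (t <= lat + half_window_ms)
        out[li] = avg.data[:, sel].mean(axis=1)
    return out
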