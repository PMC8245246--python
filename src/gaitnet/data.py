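"""Core data containers and file I/O.

The two central containers mirror how EEG toolboxes hold data: a continuous
multichannel recording with event markers, and an epoched trials x channels x
samples array with per-trial class labels. Units are microvolts throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: 32-channel extended 10-20 montage used by the gait-imagery recordings.
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT7", "FC3", "FCz", "FC4",
    "FT8", "T7", "C3", "Cz", "C4", "T8", "TP7", "TP8", "CP3", "CP4", "CPz",
    "P7", "P3", "Pz", "P4", "P8", "PO7", "PO8", "O1", "O2", "Oz",
]

#: Task labels: normal-gait imagery, hemiplegic-gait imagery, inter-trial rest.
CLASSES = ("MCI", "IEG", "REST")


@dataclass
class BandDefinition:
    """A named frequency band in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


#: Canonical EEG bands. Beta is 14-30 Hz in the band table; the narrower
#: 14-16 Hz row used in ABSP band-power summaries is kept separately.
BANDS = {
    "delta": BandDefinition("delta", 1.0, 3.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 14.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}

#: Narrow beta row reported in the absolute-power summaries.
BETA_NARROW = BandDefinition("beta_narrow", 14.0, 16.0)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz.
    labels : list of str
        Channel names; must match the channel dimension.
    events : list of (int, str)
        (sample index, class label) markers, e.g. imagery onsets.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        n = self.data.shape[1]
        for idx, _ in self.events:
            if not (0 <= idx < n):
                raise ValueError(f"event index {idx} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data, self.rate, list(self.labels), list(self.events))


@dataclass
class EpochSet:
    """Epoched trials.

    data has shape (n_trials, n_channels, n_samples); ``labels`` gives the
    class of each trial; ``t0_ms`` is the time of sample 0 relative to
    imagery onset.
    """

    data: np.ndarray
    labels: list[str]
    rate: float
    t0_ms: float = 0.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )
        if self.channel_names is not None and (
            len(self.channel_names) != self.data.shape[1]
        ):
            raise ValueError("channel_names length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.rate

    def select(self, class_label: str) -> "EpochSet":
        """Return the subset of trials with the given class label."""
        mask = np.array([lab == class_label for lab in self.labels])
        if not mask.any():
            raise ValueError(f"no trials with label {class_label!r}")
        return EpochSet(
            self.data[mask],
            [lab for lab in self.labels if lab == class_label],
            self.rate,
            self.t0_ms,
            self.channel_names,
        )

    def concatenated(self) -> np.ndarray:
        """Channels x (trials*samples) view with trials laid end to end."""
        return np.concatenate(list(self.data), axis=1)


# ---------------------------------------------------------------------------
# archives: npz payload + JSON manifest


def save_epochs(epochs: EpochSet, out_dir: str | Path, extra: dict | None = None) -> Path:
    """Write an EpochSet as ``epochs.npz`` + ``manifest.json`` in *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "epochs.npz", data=epochs.data)
    manifest = {
        "labels": list(epochs.labels),
        "rate": epochs.rate,
        "t0_ms": epochs.t0_ms,
        "channel_names": epochs.channel_names,
        "shape": list(epochs.data.shape),
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return out


def load_epochs(in_dir: str | Path) -> EpochSet:
    """Read an EpochSet archive written by :func:`save_epochs`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    data = np.load(src / "epochs.npz")["data"]
    return EpochSet(
        data,
        manifest["labels"],
        manifest["rate"],
        manifest.get("t0_ms", 0.0),
        manifest.get("channel_names"),
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# external formats


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording (annotations become events)."""
    from mne.io import read_raw_edf

    raw = read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = []
    for ann in raw.annotations:
        idx = int(round(ann["onset"] * raw.info["sfreq"]))
        if 0 <= idx < data.shape[1]:
            events.append((idx, str(ann["description"])))
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names), events)


def read_delimited(path: str | Path, sidecar: str | Path | None = None) -> EEGRecording:
    """Read a delimited numeric matrix (channels x samples) with a JSON sidecar.

    The sidecar must provide ``labels`` and ``rate`` and may provide
    ``events`` as [[sample_index, label], ...]. By default the sidecar is
    ``<path>.json``.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    meta = json.loads(Path(sidecar).read_text())
    data = np.loadtxt(path, delimiter=_sniff_delimiter(path))
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[0] != len(meta["labels"]) and data.shape[1] == len(meta["labels"]):
        data = data.T
    events = [(int(i), str(lab)) for i, lab in meta.get("events", [])]
    return EEGRecording(data, float(meta["rate"]), list(meta["labels"]), events)


def _sniff_delimiter(path: Path) -> str | None:
    first = path.open().readline()
    for d in (",", "\t", ";"):
        if d in first:
            return d
    return None  # whitespace
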