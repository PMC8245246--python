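"""The five feature families fed to the classifier.

Per trial, each family yields one value per channel (32 on the full
montage):

* ``mrcp``      — signed extremum amplitude in the 100-400 ms window
                  (per-channel phase can be appended, doubling the width);
* ``powerspec`` — 8-30 Hz band power of a per-channel Burg AR spectrum;
* ``timefreq``  — Hilbert-Huang time-frequency energy;
* ``netattr``   — nodal characteristic path length on the per-trial dDTF
                  network (unreachable nodes imputed: max finite value + 1);
* ``adjspace``  — CSP-style spatial-filter projection of the per-trial dDTF
                  weight matrix (16 components on the full montage), fitted
                  on training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import decimate as _decimate, hilbert

from .data import EpochSet
from .graphs import graph_metrics
from .mvar import MVAR, default_freq_grid, select_order_bic, stabilize
from .spectral import hht_energy


@dataclass
class FeatureTable:
    """Trials x features matrix with labels and a family tag."""

    matrix: np.ndarray
    labels: list[str]
    family: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("row count does not match label count")
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"non-finite entries in {self.family} features")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def hstack(self, other: "FeatureTable", family: str | None = None) -> "FeatureTable":
        if self.labels != other.labels:
            raise ValueError("feature tables must share trial labels")
        return FeatureTable(
            np.hstack([self.matrix, other.matrix]), list(self.labels),
            family or f"{self.family}+{other.family}",
        )


# ---------------------------------------------------------------------------
# per-trial signal features


def features_mrcp(epochs: EpochSet,
                  window_ms: tuple[float, float] = (100.0, 400.0),
                  include_phase: bool = False) -> FeatureTable:
    """Signed extremum amplitude per channel in the MRCP window, per trial."""
    t = epochs.times_ms
    sel = np.flatnonzero((t >= window_ms[0]) & (t <= window_ms[1]))
    if sel.size < 3:
        raise ValueError("MRCP window shorter than 3 samples")
    seg = epochs.data[:, :, sel]
    k = np.argmax(np.abs(seg), axis=2)  # earliest tie wins
    amps = np.take_along_axis(seg, k[:, :, None], axis=2)[:, :, 0]
    if not include_phase:
        return FeatureTable(amps, list(epochs.labels), "mrcp")
    analytic = hilbert(epochs.data, axis=2)
    idx = sel[k]
    phases = np.angle(np.take_along_axis(analytic, idx[:, :, None], axis=2))[:, :, 0]
    return FeatureTable(np.hstack([amps, phases]), list(epochs.labels), "mrcp")


def _burg_band_power(x: np.ndarray, rate: float, ar_order: int,
                     band: tuple[float, float]) -> float:
    from statsmodels.regression.linear_model import burg

    if np.var(x) == 0:
        return 0.0
    rho, sigma2 = burg(x - x.mean(), order=ar_order, demean=False)
    freqs = default_freq_grid()
    w = 2 * np.pi * freqs / rate
    denom = np.abs(1 - np.exp(-1j * np.outer(w, np.arange(1, ar_order + 1))) @ rho) ** 2
    psd = 2.0 * sigma2 / (rate * denom)  # one-sided
    selb = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[selb], freqs[selb]))


def features_powerspec_ar(epochs: EpochSet, ar_order: int = 8,
                          band: tuple[float, float] = (8.0, 30.0)) -> FeatureTable:
    """Band power of a per-channel Burg AR spectrum, per trial."""
    if ar_order < 1:
        raise ValueError("ar_order must be >= 1")
    out = np.empty((epochs.n_trials, epochs.n_channels))
    failures = []
    for ti in range(epochs.n_trials):
        for ch in range(epochs.n_channels):
            try:
                out[ti, ch] = _burg_band_power(epochs.data[ti, ch], epochs.rate,
                                               ar_order, band)
            except (np.linalg.LinAlgError, ValueError):
                out[ti, ch] = 0.0
                failures.append((ti, ch))
    if failures:
        warnings.warn(f"AR fit failed on {len(failures)} trial/channel pairs; "
                      "features set to 0")
    return FeatureTable(out, list(epochs.labels), "powerspec")


def features_hht(epochs: EpochSet, decimate: int = 4) -> FeatureTable:
    """HHT time-frequency energy per channel, per trial.

    Signals are zero-phase decimated first (EEG content lives below 45 Hz;
    sifting 3000-sample trials at full rate buys nothing but time).
    """
    if decimate > 1:
        data = _decimate(epochs.data, decimate, axis=2, zero_phase=True)
        epochs = EpochSet(data, list(epochs.labels), epochs.rate / decimate,
                          epochs.t0_ms, epochs.channel_names)
    return FeatureTable(hht_energy(epochs), list(epochs.labels), "timefreq")


# ---------------------------------------------------------------------------
# per-trial networks


@dataclass
class TrialNetworks:
    """Per-trial dDTF weight matrices and adjacencies (one MVAR per trial,
    fitted at a common BIC-selected order)."""

    weights: np.ndarray  # (n_trials, N, N)
    adjacency: np.ndarray  # (n_trials, N, N) int
    labels: list[str]
    order: int
    band: tuple[float, float]
    threshold: float
    channel_names: list[str] | None = None


def per_trial_networks(epochs: EpochSet, order: int | None = None,
                       p_max: int = 10,
                       band: tuple[float, float] = (8.0, 30.0),
                       threshold: float = 0.2,
                       normalize: str = "max") -> TrialNetworks:
    """Fit one MVAR per trial and derive its dDTF network.

    The model order is selected once by BIC on the pooled trials (the
    class-level order), then reused for every per-trial fit.
    """
    if order is None:
        order = select_order_bic(epochs, p_max=p_max).selected
    weights = np.empty((epochs.n_trials, epochs.n_channels, epochs.n_channels))
    adj = np.empty_like(weights, dtype=int)
    for ti in range(epochs.n_trials):
        res = MVAR(epochs.data[ti], order=order, rate=epochs.rate).fit()
        # short-epoch fits can be marginally unstable; shrink before H(f)
        res.process = stabilize(res.process)
        conn = res.connectivity(band=band, threshold=threshold,
                                normalize=normalize)
        weights[ti] = conn.weight
        adj[ti] = conn.adjacency
    return TrialNetworks(weights, adj, list(epochs.labels), order, band,
                         threshold, epochs.channel_names)


def features_netattr(networks: TrialNetworks, directed: bool = True) -> FeatureTable:
    """Nodal characteristic path length per channel, per trial."""
    n_trials = networks.adjacency.shape[0]
    out = np.empty((n_trials, networks.adjacency.shape[1]))
    empty = []
    for ti in range(n_trials):
        a = networks.adjacency[ti]
        if a.sum() == 0:
            empty.append(ti)
        out[ti] = graph_metrics(a, directed=directed, impute_nodal=True).nodal_pl
    if empty:
        warnings.warn(f"{len(empty)} trials yielded empty graphs; nodal path "
                      "lengths imputed")
    return FeatureTable(out, list(networks.labels), "netattr")


# ---------------------------------------------------------------------------
# adjacency-space spatial filter (CSP-style)


class AdjacencySpatialFilter:
    """Two-class spatial filter over per-trial connectivity weight matrices.

    Each trial's weight matrix W is symmetrized into a covariance-like PSD
    matrix P = (W + W^T)/2 + eps*I, trace-normalized; the generalized
    eigenproblem of the two class-mean matrices (CSP construction) gives a
    filter bank, and each trial maps to log quadratic forms log(v^T P v)
    along the top and bottom eigenvectors (those maximizing the between-class
    power ratio in either direction).

    Must be fitted on training folds only — fitting sees the labels.
    """

    def __init__(self, n_components: int = 16, eps: float = 1e-6):
        if n_components < 2 or n_components % 2:
            raise ValueError("n_components must be an even number >= 2")
        self.n_components = n_components
        self.eps = eps
        self.filters_: np.ndarray | None = None
        self.eigvals_: np.ndarray | None = None

    @staticmethod
    def _as_psd(w: np.ndarray, eps: float) -> np.ndarray:
        """Symmetrize and shift to positive definiteness, trace-normalized.

        The symmetric part of a weight matrix can have negative eigenvalues,
        so the ridge is raised above |lambda_min| rather than added blindly.
        """
        sym = (w + w.T) / 2.0
        lam_min = float(np.linalg.eigvalsh(sym)[0])
        p = sym + (max(0.0, -lam_min) + eps) * np.eye(w.shape[0])
        tr = np.trace(p)
        return p / tr if tr > 0 else p

    def fit(self, weights: np.ndarray, labels) -> "AdjacencySpatialFilter":
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if len(classes) != 2:
            raise ValueError("spatial filter is a two-class construction")
        for cls in classes:
            if (labels == cls).sum() < 2:
                raise ValueError("need >= 2 trials per class to fit")
        n = weights.shape[1]
        eps = self.eps
        from scipy.linalg import eigh

        for _ in range(6):
            ps = np.stack([self._as_psd(w, eps) for w in weights])
            c1 = ps[labels == classes[0]].mean(axis=0)
            c2 = ps[labels == classes[1]].mean(axis=0)
            try:
                evals, evecs = eigh(c1, c1 + c2)
                break
            except np.linalg.LinAlgError:
                eps *= 10.0
                warnings.warn(f"singular class means; ridge increased to {eps:g}")
        else:
            raise np.linalg.LinAlgError("spatial-filter eigenproblem failed")
        m = min(self.n_components // 2, n // 2)
        sel = np.concatenate([np.arange(m), np.arange(n - m, n)])
        self.filters_ = evecs[:, sel]
        self.eigvals_ = evals[sel]
        self._eps_used = eps
        return self

    def transform(self, weights: np.ndarray) -> np.ndarray:
        if self.filters_ is None:
            raise RuntimeError("fit before transform")
        out = np.empty((weights.shape[0], self.filters_.shape[1]))
        for ti, w in enumerate(weights):
            p = self._as_psd(w, self._eps_used)
            q = np.einsum("ij,jk,ki->i", self.filters_.T, p, self.filters_)
            out[ti] = np.log(np.clip(q, 1e-12, None))
        return out

    def fit_transform(self, weights: np.ndarray, labels) -> np.ndarray:
        return self.fit(weights, labels).transform(weights)


def features_adjspace(networks: TrialNetworks, n_components: int = 16,
                      _filter: AdjacencySpatialFilter | None = None) -> FeatureTable:
    """Adjacency-space features for a whole dataset (fits on all trials —
    use only for inspection; classification must fit per fold)."""
    f = _filter or AdjacencySpatialFilter(n_components)
    feats = f.fit_transform(networks.weights, networks.labels)
    return FeatureTable(feats, list(networks.labels), "adjspace")
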