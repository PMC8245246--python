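"""Multivariate autoregressive modelling and directed connectivity.

This is the analytical core of the package. An MVAR model

    X(t) = sum_{k=1..p} A(k) X(t-k) + E(t)

is fitted to multichannel EEG by pooled least squares (pooling epochs without
letting regressors straddle trial boundaries). From the fitted coefficients
the spectral transfer matrix H(f) = A(f)^-1 is formed with

    A(f) = I - sum_{k=1..p} A(k) exp(-i 2 pi f k / rate),

and three frequency-domain couplings are derived per ordered channel pair
(row = sink, column = source):

* full-frequency DTF  F2_ij(f) = |H_ij(f)|^2 / sum_{f,k} |H_ik(f)|^2,
  normalized per sink over the whole frequency grid, so
  sum_{j,f} F2_ij(f) = 1 for every row i;
* partial coherence   C_ij(f), from minors of the spectral matrix
  S(f) = H(f) Sigma H(f)^H — equivalently from its inverse;
* direct DTF          chi2_ij(f) = F2_ij(f) * C_ij(f)^2,
  which suppresses influence mediated through third channels.

Band-averaged dDTF forms a weighted directed graph; thresholding it yields
the binary adjacency analyzed by :mod:`gaitnet.graphs`.

The public surface follows the Model/Results convention: build an
:class:`MVAR` from data, call :meth:`MVAR.fit` to obtain
:class:`MVARResults`, and derive :class:`SpectralTransfer` /
:class:`ConnectivityResult` from the results object. The module-level
functions expose the same steps for functional use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .data import EpochSet

__all__ = [
    "VARProcess",
    "MVAR",
    "MVARResults",
    "OrderSelection",
    "SpectralTransfer",
    "ConnectivityResult",
    "fit_mvar",
    "select_order_bic",
    "transfer_matrix",
    "full_freq_dtf",
    "partial_coherence",
    "ddtf",
    "build_network",
    "default_freq_grid",
]


class UnstableModelError(ValueError):
    """Raised when an operation requires a stable MVAR process."""


class SingularTransferError(np.linalg.LinAlgError):
    """A(f) or S(f) was singular at some frequency."""

    def __init__(self, freq_hz: float, what: str = "A(f)"):
        self.freq_hz = freq_hz
        super().__init__(f"{what} singular at {freq_hz:g} Hz")


@dataclass
class VARProcess:
    """A vector-autoregressive process: coefficients A(1..p) and noise covariance.

    ``coeffs`` has shape (p, N, N); ``noise_cov`` is the covariance of the
    Gaussian innovations E(t), shape (N, N), symmetric positive semi-definite.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, N, N)")
        n = self.coeffs.shape[1]
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise_cov shape mismatch")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() < -1e-10:
            raise ValueError("noise_cov must be positive semi-definite")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def companion(self) -> np.ndarray:
        """Companion matrix of the lag polynomial (shape (N*p, N*p))."""
        p, n = self.order, self.n_channels
        top = self.coeffs.transpose(1, 0, 2).reshape(n, n * p)
        comp = np.zeros((n * p, n * p))
        comp[:n] = top
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return comp

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


@dataclass
class OrderSelection:
    """BIC curve over candidate orders; ``selected`` is the argmin (ties -> smallest)."""

    orders: np.ndarray
    bic: np.ndarray
    selected: int


@dataclass
class SpectralTransfer:
    """Frequency-domain description of a fitted MVAR process.

    ``A_f``, ``H_f`` and ``S_f`` are (n_freqs, N, N) complex arrays: the
    Fourier-transformed lag polynomial, the transfer matrix H = A^-1, and the
    spectral matrix S = H Sigma H^H (spectra on the diagonal, cross-spectra
    off it).
    """

    freqs: np.ndarray
    A_f: np.ndarray
    H_f: np.ndarray
    S_f: np.ndarray


@dataclass
class ConnectivityResult:
    """Directed-connectivity arrays and the derived graph.

    All (n_freqs, N, N) arrays use the sink-row / source-column convention:
    entry [f, i, j] quantifies flow j -> i at frequency f. ``weight`` is the
    band-mean dDTF (normalized per ``normalization``); ``adjacency`` is
    ``weight >= threshold`` with a forced-zero diagonal.
    """

    freqs: np.ndarray
    ffdtf: np.ndarray
    pcoh: np.ndarray
    ddtf: np.ndarray
    weight: np.ndarray
    adjacency: np.ndarray
    threshold: float
    band: tuple[float, float]
    normalization: str = "max"
    weight_raw: np.ndarray | None = None

    def summary(self) -> str:
        n = self.weight.shape[0]
        n_edges = int(self.adjacency.sum())
        lines = [
            "Directed connectivity (dDTF)",
            "=" * 34,
            f"channels:          {n}",
            f"frequency grid:    {self.freqs[0]:g}-{self.freqs[-1]:g} Hz "
            f"({len(self.freqs)} points)",
            f"aggregation band:  {self.band[0]:g}-{self.band[1]:g} Hz",
            f"weight scaling:    {self.normalization}",
            f"threshold:         {self.threshold:g}",
            f"edges:             {n_edges} / {n * (n - 1)} possible",
        ]
        return "\n".join(lines)


def default_freq_grid() -> np.ndarray:
    """1 Hz spacing, 1..45 Hz — the grid used throughout the pipeline."""
    return np.arange(1.0, 46.0)


# ---------------------------------------------------------------------------
# estimation


def _as_trials(data) -> list[np.ndarray]:
    if isinstance(data, EpochSet):
        return [np.asarray(tr, dtype=float) for tr in data.data]
    arr_like = data
    if isinstance(arr_like, np.ndarray) and arr_like.ndim == 2:
        return [np.asarray(arr_like, dtype=float)]
    if isinstance(arr_like, np.ndarray) and arr_like.ndim == 3:
        return [np.asarray(tr, dtype=float) for tr in arr_like]
    return [np.asarray(tr, dtype=float) for tr in arr_like]


def _stack_regression(trials: list[np.ndarray], order: int):
    """Build pooled (Y, Z) so that Y = B Z with B = [A(1) ... A(p)].

    Regressors are formed within each trial only, so no lagged window
    straddles a trial boundary.
    """
    ys, zs = [], []
    for x in trials:
        n, t = x.shape
        if t <= order:
            continue
        ys.append(x[:, order:])
        zs.append(
            np.concatenate([x[:, order - k : t - k] for k in range(1, order + 1)], axis=0)
        )
    if not ys:
        raise ValueError("no trial longer than the model order")
    return np.concatenate(ys, axis=1), np.concatenate(zs, axis=1)


def fit_mvar(data, order: int) -> VARProcess:
    """Least-squares MVAR fit pooled across trials.

    Parameters
    ----------
    data : EpochSet, (N, T) array, (trials, N, T) array, or list of (N, T)
    order : int
        Model order p (number of lags).

    Returns
    -------
    VARProcess
        Estimated A(1..p) and the maximum-likelihood innovation covariance
        (residual covariance normalized by the number of regression rows).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    trials = _as_trials(data)
    n = trials[0].shape[0]
    y, z = _stack_regression(trials, order)
    nobs = y.shape[1]
    if nobs < n * order:
        raise ValueError(f"only {nobs} usable samples for {n * n * order} coefficients")
    b, _, rank, _ = np.linalg.lstsq(z.T, y.T, rcond=None)
    if rank < z.shape[0]:
        raise np.linalg.LinAlgError("rank-deficient regressor matrix")
    b = b.T  # (N, N*p)
    resid = y - b @ z
    sigma = (resid @ resid.T) / nobs
    coeffs = b.reshape(n, order, n).transpose(1, 0, 2)
    return VARProcess(coeffs, sigma)


def select_order_bic(data, p_max: int = 20) -> OrderSelection:
    """Choose the MVAR order by the Bayesian information criterion.

    For each p in 1..p_max the model is refitted and
    ``BIC(p) = ln det(Sigma_p) + ln(n_obs) * N^2 p / n_obs`` evaluated on
    that fit's own regression sample. Ties go to the smallest order.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    trials = _as_trials(data)
    n = trials[0].shape[0]
    orders = np.arange(1, p_max + 1)
    bics = np.full(p_max, np.inf)
    for i, p in enumerate(orders):
        try:
            y, z = _stack_regression(trials, int(p))
        except ValueError:
            break
        nobs = y.shape[1]
        if nobs <= z.shape[0]:
            break
        b, _, _, _ = np.linalg.lstsq(z.T, y.T, rcond=None)
        resid = y - b.T @ z
        sigma = (resid @ resid.T) / nobs
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        bics[i] = logdet + np.log(nobs) * (n * n * p) / nobs
    selected = int(orders[int(np.argmin(bics))])
    return OrderSelection(orders, bics, selected)


def stabilize(process: VARProcess, target_radius: float = 0.99) -> VARProcess:
    """Shrink a (marginally) unstable process to stability.

    Scaling A(k) by g^k scales every companion eigenvalue by g exactly, so a
    single step suffices. Needed for per-trial fits on short epochs, where
    sampling noise can push the spectral radius just past 1. Stable inputs
    are returned unchanged.
    """
    rad = process.spectral_radius
    if rad < target_radius:
        return process
    g = target_radius / rad
    scale = g ** np.arange(1, process.order + 1)
    return VARProcess(process.coeffs * scale[:, None, None], process.noise_cov)


# ---------------------------------------------------------------------------
# frequency domain


def transfer_matrix(process: VARProcess, freqs: np.ndarray | None = None,
                    rate_hz: float = 1000.0) -> SpectralTransfer:
    """Compute A(f), H(f) = A(f)^-1 and S(f) = H Sigma H^H on a grid.

    Frequencies are in Hz and normalized internally by ``rate_hz``. Raises
    :class:`UnstableModelError` for an unstable process and
    :class:`SingularTransferError` if A(f) cannot be inverted at some
    frequency.
    """
    if not process.is_stable:
        raise UnstableModelError(
            f"companion spectral radius {process.spectral_radius:.3f} >= 1"
        )
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    p, n = process.order, process.n_channels
    k = np.arange(1, p + 1)
    # phase[f, k] = exp(-i 2 pi f k / rate)
    phase = np.exp(-2j * np.pi * np.outer(freqs / rate_hz, k))
    a_f = np.eye(n)[None, :, :] - np.einsum("fk,kij->fij", phase, process.coeffs)
    h_f = np.empty_like(a_f)
    for fi in range(len(freqs)):
        try:
            h_f[fi] = np.linalg.inv(a_f[fi])
        except np.linalg.LinAlgError:
            raise SingularTransferError(freqs[fi]) from None
    s_f = h_f @ process.noise_cov @ np.conj(h_f).transpose(0, 2, 1)
    return SpectralTransfer(freqs, a_f, h_f, s_f)


def full_freq_dtf(transfer: SpectralTransfer) -> np.ndarray:
    """Full-frequency DTF: |H_ij(f)|^2 normalized per sink row over the whole grid.

    The denominator for row i is the sum of |H_ik(f)|^2 over every grid
    frequency and every source k, so each row's entries sum to exactly 1
    across sources and frequencies.
    """
    h2 = np.abs(transfer.H_f) ** 2  # (F, N, N)
    denom = h2.sum(axis=(0, 2))  # per sink row i
    if np.any(denom <= 0):
        raise ZeroDivisionError("all-zero transfer row: degenerate model")
    return h2 / denom[None, :, None]


def partial_coherence(transfer: SpectralTransfer) -> np.ndarray:
    """Partial coherence |C_ij(f)| in [0, 1] from minors of the spectral matrix.

    C_ij = M_ij / sqrt(M_ii M_jj), where M_ij is the minor of S(f) with row i
    and column j removed. Computed via the inverse spectral matrix: the
    cofactor identity M_ij = +/- det(S) (S^-1)_ji makes det(S) cancel, giving
    |C_ij| = |(S^-1)_ji| / sqrt((S^-1)_ii (S^-1)_jj).
    """
    n = transfer.S_f.shape[1]
    if n < 2:
        raise ValueError("partial coherence needs at least 2 channels")
    out = np.empty(transfer.S_f.shape)
    for fi, s in enumerate(transfer.S_f):
        try:
            g = np.linalg.inv(s)
        except np.linalg.LinAlgError:
            raise SingularTransferError(transfer.freqs[fi], "S(f)") from None
        d = np.sqrt(np.clip(np.real(np.diag(g)), 0.0, None))
        denom = np.outer(d, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.abs(g.T) / denom
        out[fi] = np.nan_to_num(c, nan=0.0, posinf=0.0)
    return np.clip(out, 0.0, 1.0)


def ddtf(ffdtf_arr: np.ndarray, pcoh_arr: np.ndarray) -> np.ndarray:
    """Direct DTF: elementwise F2_ij(f) * C_ij(f)^2."""
    if ffdtf_arr.shape != pcoh_arr.shape:
        raise ValueError("shape mismatch between ffDTF and partial coherence")
    return ffdtf_arr * pcoh_arr**2


def build_network(ddtf_arr: np.ndarray, freqs: np.ndarray,
                  band: tuple[float, float] = (8.0, 30.0),
                  threshold: float = 0.2,
                  normalize: str = "max"):
    """Aggregate dDTF over a band and threshold into a binary adjacency.

    ``weight[i, j]`` is the mean dDTF over the band frequencies for flow
    j -> i. With ``normalize="max"`` (default) the weight matrix is rescaled
    by its largest off-diagonal entry before thresholding, so weights lie in
    [0, 1] and the 0.2 threshold selects edges relative to the strongest
    connection; ``normalize="none"`` thresholds the raw band-mean values.

    Returns ``(weight, adjacency, weight_raw)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"no grid frequencies inside band {band}")
    weight_raw = ddtf_arr[sel].mean(axis=0)
    weight = weight_raw.copy()
    if normalize == "max":
        off = ~np.eye(weight.shape[0], dtype=bool)
        m = weight[off].max()
        if m > 0:
            weight = weight / m
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    adjacency = (weight >= threshold).astype(int)
    np.fill_diagonal(adjacency, 0)
    return weight, adjacency, weight_raw


# ---------------------------------------------------------------------------
# Model / Results


class MVAR:
    """Multivariate autoregressive model of multichannel EEG.

    Parameters
    ----------
    endog : EpochSet, (N, T) array, (trials, N, T) array, or list of (N, T)
        The observed series; epochs are pooled in estimation.
    order : int, optional
        Model order p. If None, :meth:`fit` selects it by BIC.
    rate : float
        Sampling rate in Hz (used for the frequency axis of connectivity).
    channel_names : list of str, optional

    Examples
    --------
    >>> model = MVAR(epochs.select("MCI"), rate=epochs.rate)
    >>> res = model.fit()
    >>> conn = res.connectivity(band=(8, 30), threshold=0.2)
    """

    def __init__(self, endog, order: int | None = None, rate: float = 1000.0,
                 channel_names: list[str] | None = None):
        if isinstance(endog, EpochSet):
            rate = endog.rate
            if channel_names is None:
                channel_names = endog.channel_names
        self.trials = _as_trials(endog)
        self.order = order
        self.rate = float(rate)
        self.n_channels = self.trials[0].shape[0]
        self.channel_names = channel_names

    @classmethod
    def from_epochs(cls, epochs: EpochSet, class_label: str | None = None,
                    order: int | None = None) -> "MVAR":
        """Build a model from an EpochSet, optionally restricted to one class."""
        if class_label is not None:
            epochs = epochs.select(class_label)
        return cls(epochs, order=order)

    def select_order(self, p_max: int = 20) -> OrderSelection:
        return select_order_bic(self.trials, p_max=p_max)

    def fit(self, order: int | None = None, p_max: int = 20) -> "MVARResults":
        """Estimate the coefficients; selects the order by BIC when unset."""
        p = order or self.order
        selection = None
        if p is None:
            selection = self.select_order(p_max)
            p = selection.selected
        process = fit_mvar(self.trials, p)
        y, z = _stack_regression(self.trials, p)
        return MVARResults(self, process, nobs=y.shape[1], order_selection=selection)


@dataclass
class MVARResults:
    """Fitted MVAR model: coefficient matrices, innovation covariance, diagnostics."""

    model: MVAR
    process: VARProcess
    nobs: int
    order_selection: OrderSelection | None = None
    _transfer_cache: dict = field(default_factory=dict, repr=False)

    @property
    def coeffs(self) -> np.ndarray:
        return self.process.coeffs

    @property
    def sigma_u(self) -> np.ndarray:
        return self.process.noise_cov

    @property
    def order(self) -> int:
        return self.process.order

    @property
    def bic(self) -> float:
        n, p = self.process.n_channels, self.order
        sign, logdet = np.linalg.slogdet(self.sigma_u)
        return float(logdet + np.log(self.nobs) * (n * n * p) / self.nobs)

    def transfer(self, freqs: np.ndarray | None = None) -> SpectralTransfer:
        key = None if freqs is None else tuple(np.asarray(freqs).tolist())
        if key not in self._transfer_cache:
            self._transfer_cache[key] = transfer_matrix(
                self.process, freqs, rate_hz=self.model.rate
            )
        return self._transfer_cache[key]

    def connectivity(self, band: tuple[float, float] = (8.0, 30.0),
                     threshold: float = 0.2,
                     freqs: np.ndarray | None = None,
                     normalize: str = "max") -> ConnectivityResult:
        """Full dDTF pipeline: H(f) -> ffDTF, partial coherence, dDTF, graph."""
        tr = self.transfer(freqs)
        f2 = full_freq_dtf(tr)
        pc = partial_coherence(tr)
        chi2 = ddtf(f2, pc)
        weight, adjacency, weight_raw = build_network(
            chi2, tr.freqs, band=band, threshold=threshold, normalize=normalize
        )
        return ConnectivityResult(
            freqs=tr.freqs, ffdtf=f2, pcoh=pc, ddtf=chi2, weight=weight,
            adjacency=adjacency, threshold=threshold, band=band,
            normalization=normalize, weight_raw=weight_raw,
        )

    def summary(self) -> str:
        p, n = self.order, self.process.n_channels
        lines = [
            "MVAR model results",
            "=" * 34,
            f"channels (N):      {n}",
            f"order (p):         {p}"
            + (" (BIC-selected)" if self.order_selection is not None else ""),
            f"observations:      {self.nobs}",
            f"coefficients:      {n * n * p}",
            f"BIC:               {self.bic:.4f}",
            f"spectral radius:   {self.process.spectral_radius:.4f}",
            f"stable:            {self.process.is_stable}",
            f"ln det(Sigma_u):   {np.linalg.slogdet(self.sigma_u)[1]:.4f}",
        ]
        return "\n".join(lines)
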