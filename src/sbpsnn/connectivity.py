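"""Directed spectral Granger connectivity and band-limited coherence.

Pairwise Geweke spectral Granger causality from an OLS-fitted bivariate
VAR (default order 20, matching common EEG practice), evaluated at
integer frequencies; directed networks retain band-averaged edges that
exceed a trial-shuffle surrogate threshold.  A Welch magnitude-squared
coherence summary per electrode pair and band stands in for factor-based
cross-spectral analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig


# ---------------------------------------------------------------------------
# VAR fitting
# ---------------------------------------------------------------------------


def fit_var(x: np.ndarray, order: int):
    """OLS fit of a VAR(order) to (channels, samples) data.

    Returns (A, Sigma, resid): coefficient array (order, k, k), innovation
    covariance (k, k) and residuals.  Raises on unstable fits (companion
    spectral radius >= 1) and on insufficient samples.
    """
    x = np.asarray(x, dtype=float)
    k, n = x.shape
    if n < 10 * order * k:
        raise ValueError(f"need at least {10 * order * k} samples for "
                         f"VAR({order}) on {k} channels, got {n}")
    x = x - x.mean(axis=1, keepdims=True)
    Y = x[:, order:].T                                   # (n-order, k)
    Z = np.hstack([x[:, order - lag:n - lag].T for lag in range(1, order + 1)])
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)            # (order*k, k)
    A = B.T.reshape(k, order, k).transpose(1, 0, 2)      # (order, k, k)
    resid = Y - Z @ B
    Sigma = resid.T @ resid / (len(Y) - order * k)
    comp = np.zeros((k * order, k * order))
    comp[:k, :] = np.concatenate(A, axis=1)
    if order > 1:
        comp[k:, :-k] = np.eye(k * (order - 1))
    if np.max(np.abs(np.linalg.eigvals(comp))) >= 1.0:
        raise ValueError("unstable VAR fit (companion spectral radius >= 1)")
    return A, Sigma, resid


def var_transfer(A: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Transfer function H(f) = (I - sum_l A_l e^{-i 2 pi f l / fs})^{-1}."""
    order, k, _ = A.shape
    H = np.empty((len(freqs), k, k), dtype=complex)
    for i, f in enumerate(freqs):
        Af = np.eye(k, dtype=complex)
        for lag in range(1, order + 1):
            Af -= A[lag - 1] * np.exp(-2j * np.pi * f * lag / fs)
        H[i] = np.linalg.inv(Af)
    return H


def _pair_spectral_gc(x: np.ndarray, fs: float, order: int,
                      freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geweke spectral GC for a channel pair; returns (gc_xy, gc_yx).

    With the bivariate spectrum S = H Sigma H*, the y-spectrum splits
    into the part carried by y's own innovation (via the corrected
    transfer entry) and the part driven by x's partialised innovation;
    GC(x->y; f) = ln( S_yy / (|H_yy + (Sxy/Syy) H_yx|^2 Syy) ), and
    symmetrically for y->x.
    """
    A, Sigma, _ = fit_var(x, order)
    H = var_transfer(A, freqs, fs)
    S = np.einsum("fij,jk,flk->fil", H, Sigma, H.conj())

    def gc(src, dst):
        s_dd = S[:, dst, dst].real
        corr = Sigma[src, dst] / Sigma[dst, dst]
        h_eff = H[:, dst, dst] + corr * H[:, dst, src]
        intrinsic = (np.abs(h_eff) ** 2) * Sigma[dst, dst]
        ratio = np.maximum(s_dd, 1e-300) / np.maximum(intrinsic, 1e-300)
        return np.log(np.maximum(ratio, 1.0))

    return gc(0, 1), gc(1, 0)


@dataclass
class GCMatrix:
    """Directed source x sink x frequency Granger-causality values."""

    values: np.ndarray
    electrodes: tuple[str, ...]
    freqs: np.ndarray
    order: int = 20

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.electrodes)
        if self.values.shape != (n, n, len(self.freqs)):
            raise ValueError("values must be (n, n, n_freqs)")
        if np.any(self.values[~np.eye(n, dtype=bool)] < 0):
            raise ValueError("GC values must be non-negative")

    def pair(self, src: str, dst: str) -> np.ndarray:
        return self.values[self.electrodes.index(src), self.electrodes.index(dst)]

    def band_mean(self, band: tuple[float, float]) -> np.ndarray:
        sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        return self.values[:, :, sel].mean(axis=2)


def spectral_granger(data: np.ndarray, fs: float, electrodes=None,
                     order: int = 20, freqs=None) -> GCMatrix:
    """Pairwise-conditional Geweke spectral GC over all directed pairs.

    ``data`` is (channels, samples) or a list of per-trial (channels,
    samples) arrays (trials are concatenated for the VAR fit after
    per-trial demeaning).  Frequencies default to the integers 1-48 Hz.
    """
    if isinstance(data, (list, tuple)):
        data = np.concatenate([np.asarray(d, dtype=float)
                               - np.asarray(d, dtype=float).mean(axis=1, keepdims=True)
                               for d in data], axis=1)
    data = np.asarray(data, dtype=float)
    k = data.shape[0]
    if electrodes is None:
        electrodes = tuple(f"ch{i}" for i in range(k))
    if freqs is None:
        freqs = np.arange(1.0, min(49.0, fs / 2))
    freqs = np.asarray(freqs, dtype=float)
    values = np.zeros((k, k, len(freqs)))
    for i in range(k):
        for j in range(i + 1, k):
            gc_ij, gc_ji = _pair_spectral_gc(data[[i, j]], fs, order, freqs)
            values[i, j] = gc_ij
            values[j, i] = gc_ji
    return GCMatrix(values, tuple(electrodes), freqs, order)


# ---------------------------------------------------------------------------
# directed network extraction with surrogate thresholding
# ---------------------------------------------------------------------------


@dataclass
class DirectedNetwork:
    edges: list = field(default_factory=list)   # (src, dst, band, strength)
    thresholds: dict = field(default_factory=dict)
    band: str = ""


def directed_network(trials, fs: float, electrodes, band: tuple[float, float],
                     band_name: str = "", order: int = 20,
                     n_surrogates: int = 20, alpha: float = 0.05,
                     threshold: float | None = None,
                     seed: int = 0) -> DirectedNetwork:
    """Band-averaged directed GC edges exceeding a trial-shuffle null.

    ``trials`` is a list of (channels, samples) arrays.  Surrogates
    shuffle the source channel's trial assignment (breaking cross-channel
    coupling while preserving each channel's autostructure); an edge is
    kept when its band-mean GC exceeds the (1 - alpha) quantile of its
    surrogate distribution.  A fixed ``threshold`` replaces the surrogate
    rule when given.
    """
    rng = np.random.default_rng(seed)
    freqs = np.arange(max(1.0, band[0]), min(band[1], fs / 2 - 1) + 1)
    gc = spectral_granger(trials, fs, electrodes, order, freqs)
    strength = gc.band_mean(band)

    if threshold is not None:
        net = DirectedNetwork(band=band_name)
        for i, src_e in enumerate(electrodes):
            for j, dst in enumerate(electrodes):
                if i != j:
                    net.thresholds[(src_e, dst)] = float(threshold)
                    if strength[i, j] > threshold:
                        net.edges.append((src_e, dst, band_name,
                                          float(strength[i, j])))
        return net
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")

    n_tr = len(trials)
    k = len(electrodes)
    null = np.zeros((n_surrogates, k, k))
    for s in range(n_surrogates):
        perm = rng.permutation(n_tr)
        while n_tr > 1 and np.all(perm == np.arange(n_tr)):
            perm = rng.permutation(n_tr)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                pair_trials = [np.vstack([trials[perm[t]][i], trials[t][j]])
                               for t in range(n_tr)]
                g = spectral_granger(pair_trials, fs, (electrodes[i],
                                                       electrodes[j]),
                                     order, freqs)
                null[s, i, j] = g.band_mean(band)[0, 1]
    thr = np.quantile(null, 1 - alpha, axis=0)

    net = DirectedNetwork(band=band_name)
    for i, src in enumerate(electrodes):
        for j, dst in enumerate(electrodes):
            if i == j:
                continue
            net.thresholds[(src, dst)] = float(thr[i, j])
            if strength[i, j] > thr[i, j]:
                net.edges.append((src, dst, band_name, float(strength[i, j])))
    return net


# ---------------------------------------------------------------------------
# coherence summary (stand-in for factor-based cross-spectral analysis)
# ---------------------------------------------------------------------------


def coherence_summary(data: np.ndarray, fs: float, electrodes,
                      bands: dict[str, tuple[float, float]] | None = None,
                      nperseg: int | None = None):
    """Welch magnitude-squared coherence per electrode pair and band.

    Returns {(e1, e2): {band: coherence}} with values in [0, 1]; the
    measure is symmetric in pair order.
    """
    from sbpsnn.preprocess import BANDS

    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least two electrodes")
    bands = bands or BANDS
    if nperseg is None:
        nperseg = min(data.shape[1], int(2 * fs))
    if nperseg > data.shape[1]:
        raise ValueError("segment length exceeds the data")
    out = {}
    for i in range(data.shape[0]):
        for j in range(i + 1, data.shape[0]):
            f, coh = sig.coherence(data[i], data[j], fs=fs, nperseg=nperseg)
            row = {}
            for name, (lo, hi) in bands.items():
                sel = (f >= lo) & (f <= hi)
                row[name] = float(np.clip(coh[sel].mean(), 0.0, 1.0))
            out[(electrodes[i], electrodes[j])] = row
    return out
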