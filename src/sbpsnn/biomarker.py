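"""Frequency-band biomarker attribution.

Two complementary attributions of the decodable signal to the five
canonical bands: (i) per-band decoding — the band-filtered signal is
re-encoded to spikes and classified with the standard spiking decoder;
(ii) EasyMKL — a margin-optimal convex combination of one linear kernel
per band (Aiolli & Donini's formulation), whose learned kernel weights,
normalised to percent, serve as band contributions.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sig
from scipy.optimize import minimize

from sbpsnn.encode import encode_threshold
from sbpsnn.evaluation import evaluate, stratified_split
from sbpsnn.preprocess import BAND_ORDER, BANDS
from sbpsnn.snn import EmotionDecoder, TrainConfig

# ---------------------------------------------------------------------------
# per-band decoding with the spiking decoder
# ---------------------------------------------------------------------------


def band_filter_dataset(dataset, electrodes, band: str, k: float = 0.5):
    """Band-filter every trial to one canonical band and spike-encode it.

    The encoding threshold is pooled over trials per channel, as in the
    broadband task, so band-power differences survive as rate
    differences.
    """
    if band not in BANDS:
        raise KeyError(f"unknown band {band!r}")
    lo, hi = BANDS[band]
    fs = dataset.recordings[0].fs
    sos = sig.butter(4, [lo, min(hi, 0.45 * fs)], btype="bandpass", fs=fs,
                     output="sos")
    picked = [rec.pick(electrodes) for rec in dataset.recordings]
    filtered = [sig.sosfiltfilt(sos, rec.data, axis=1) for rec in picked]
    pooled = np.concatenate([np.diff(x, axis=1) for x in filtered], axis=1)
    theta = k * pooled.std(axis=1)
    theta = np.where(theta <= 0, 1.0, theta)
    return [encode_threshold(x, dt=1.0 / fs, labels=tuple(electrodes),
                             theta=theta) for x in filtered]


def band_decode(dataset, labels, electrodes, band: str, train_idx, test_idx,
                montage, cfg: TrainConfig | None = None, **model_kwargs):
    """Decode one band: band-filter, re-encode, train, score held-out split."""
    tensors = band_filter_dataset(dataset, electrodes, band)
    cfg = cfg or TrainConfig()
    tr_x = [tensors[i] for i in train_idx]
    tr_y = [labels[i] for i in train_idx]
    te_x = [tensors[i] for i in test_idx]
    te_y = [labels[i] for i in test_idx]
    model = EmotionDecoder(tr_x, tr_y, electrodes=tuple(electrodes),
                           montage=montage, **model_kwargs)
    fit = model.fit(cfg)
    rep = evaluate(fit.predict(te_x), te_y,
                   task="binary" if len(model.classes) == 2 else "four_class")
    return rep


def band_decode_all(dataset, labels, electrodes, train_idx, test_idx, montage,
                    cfg: TrainConfig | None = None, **model_kwargs) -> dict:
    """Per-band (accuracy, f1) for all five canonical bands."""
    out = {}
    for band in BAND_ORDER:
        rep = band_decode(dataset, labels, electrodes, band, train_idx,
                          test_idx, montage, cfg, **model_kwargs)
        out[band] = (rep.accuracy, rep.f1)
    return out


# ---------------------------------------------------------------------------
# EasyMKL
# ---------------------------------------------------------------------------


def _trace_normalise(K: np.ndarray) -> np.ndarray:
    tr = np.trace(K)
    if tr <= 0:
        raise ValueError("degenerate kernel (non-positive trace)")
    return K * (len(K) / tr)


def easymkl(kernels, y, lam: float = 0.2):
    """EasyMKL kernel-weight learning for a binary problem.

    Solves the KOMD-style margin problem on the sum kernel over the
    product of class probability simplices,

        min_gamma (1 - lam) * gamma' Y K Y gamma + lam ||gamma||^2,

    with sum(gamma_i : y_i = +1) = 1 and sum(gamma_i : y_i = -1) = 1,
    gamma >= 0; each kernel's weight is its induced margin component
    eta_r = gamma' Y K_r Y gamma, normalised to sum to one.  Returns
    (weights, gamma).
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be +-1")
    if len(set(y)) < 2:
        raise ValueError("need both classes")
    Ks = [_trace_normalise(np.asarray(K, dtype=float)) for K in kernels]
    Ksum = sum(Ks)
    n = len(y)
    Y = np.diag(y)
    Q = (1 - lam) * (Y @ Ksum @ Y) + lam * np.eye(n)
    Q = 0.5 * (Q + Q.T)

    pos = y > 0
    gamma0 = np.where(pos, 1.0 / pos.sum(), 1.0 / (~pos).sum())

    cons = [{"type": "eq", "fun": lambda g, m=pos: g[m].sum() - 1.0},
            {"type": "eq", "fun": lambda g, m=~pos: g[m].sum() - 1.0}]
    res = minimize(lambda g: g @ Q @ g, gamma0, jac=lambda g: 2 * Q @ g,
                   bounds=[(0.0, 1.0)] * n, constraints=cons,
                   method="SLSQP", options={"maxiter": 200, "ftol": 1e-10})
    gamma = np.clip(res.x, 0.0, None)
    eta = np.array([float(gamma @ Y @ K @ Y @ gamma) for K in Ks])
    eta = np.clip(eta, 0.0, None)
    if eta.sum() <= 0:
        eta = np.ones(len(Ks))
    return eta / eta.sum(), gamma


def band_feature_blocks(dataset, labels, electrodes, frame_hop: float = 0.1,
                        n_freqs: int = 24) -> dict[str, np.ndarray]:
    """Per-band flattened band-power feature matrices (trials x features)."""
    from sbpsnn.preprocess import wavelet_band_power

    blocks: dict[str, list] = {b: [] for b in BAND_ORDER}
    for rec in dataset.recordings:
        bp = wavelet_band_power(rec.pick(electrodes), frame_hop=frame_hop,
                                n_freqs=n_freqs)
        for b in BAND_ORDER:
            blocks[b].append(bp.band(b).ravel())
    return {b: np.asarray(v) for b, v in blocks.items()}


def easymkl_contributions(feature_blocks: dict[str, np.ndarray], labels,
                          lam: float = 0.2) -> dict:
    """Band contributions in percent from EasyMKL kernel weights.

    One trace-normalised linear kernel per band; binary problems use the
    labels directly, multi-class problems average one-vs-rest weight
    vectors.  Contributions are >= 0 and sum to 100.
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    bands = list(feature_blocks)
    Xs = {b: np.asarray(X, dtype=float) for b, X in feature_blocks.items()}
    n = len(labels)
    for b, X in Xs.items():
        if len(X) != n:
            raise ValueError("feature block / label length mismatch")
        X = X - X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, keepdims=True)
        Xs[b] = X / np.where(sd < 1e-12, 1.0, sd)
    kernels = [Xs[b] @ Xs[b].T for b in bands]

    lbl = np.asarray(labels)
    if len(classes) == 2:
        y = np.where(lbl == classes[1], 1.0, -1.0)
        weights, _ = easymkl(kernels, y, lam)
    else:
        ws = []
        for c in classes:
            y = np.where(lbl == c, 1.0, -1.0)
            w, _ = easymkl(kernels, y, lam)
            ws.append(w)
        weights = np.mean(ws, axis=0)
        weights = weights / weights.sum()
    return {b: float(100.0 * w) for b, w in zip(bands, weights)}
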