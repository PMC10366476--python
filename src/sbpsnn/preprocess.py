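"""EEG cleaning and time-frequency decomposition.

The cleaning chain follows standard emotional-EEG practice: zero-phase
Butterworth band-pass 0.5-48 Hz, Infomax ICA with automatic rejection of
ocular components, common-average re-referencing, and 500 ms pre-stimulus
baseline correction.  Band powers are computed with a complex Morlet
continuous wavelet transform and averaged inside the five canonical bands
delta (0.5-4), theta (4-8), alpha (8-12), beta (12-30) and gamma
(30-48 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 48.0),
}
BAND_ORDER = tuple(BANDS)


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples (microvolt), with markers.

    ``events`` is a list of ``(onset_sample, code)`` pairs; stimulus onsets
    use code ``"stim"``, simulated blink artifacts ``"blink"``.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    events: list[tuple[int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("channel count does not match label count")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = tuple(self.labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def pick(self, labels) -> "EEGRecording":
        idx = [self.labels.index(lbl) for lbl in labels]
        return replace(self, data=self.data[idx], labels=tuple(labels))


@dataclass
class BandPower:
    """Non-negative band power, channels x bands x frames."""

    power: np.ndarray
    bands: tuple[str, ...] = BAND_ORDER
    frame_hop: float = 0.1

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be channels x bands x frames")
        if self.power.shape[1] != len(self.bands):
            raise ValueError("band axis does not match band names")
        if np.any(self.power < 0):
            raise ValueError("band power must be non-negative")

    def band(self, name: str) -> np.ndarray:
        return self.power[:, self.bands.index(name), :]


def bandpass(rec: EEGRecording, low: float = 0.5, high: float = 48.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth band-pass filter."""
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if rec.fs <= 2 * high:
        raise ValueError(f"fs={rec.fs} too low for a {high} Hz band edge")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Common-average reference: subtract the instantaneous channel mean."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def remove_artifacts_ica(rec: EEGRecording, frontal_refs=("Fp1", "Fp2"),
                         corr_threshold: float = 0.7,
                         seed: int = 0) -> EEGRecording:
    """Infomax ICA with automatic ocular-component rejection.

    Components whose absolute Pearson correlation with the frontal
    reference composite (mean of ``frontal_refs``) exceeds
    ``corr_threshold`` are zeroed before reconstruction.  The number of
    removed components is stored in ``meta["ica_removed"]``; a failed
    decomposition returns the input unchanged with
    ``meta["ica_failed"] = True``.
    """
    from mne.preprocessing import infomax

    if corr_threshold <= 0:
        raise ValueError("corr_threshold must be positive")
    refs = [lbl for lbl in frontal_refs if lbl in rec.labels]
    if not refs:
        raise ValueError("no frontal reference channel present")
    composite = np.mean([rec.channel(lbl) for lbl in refs], axis=0)

    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    try:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        # rank-truncated whitening: average-referenced data loses one
        # dimension; keep only well-conditioned components
        keep = s > 1e-8 * s.max()
        if keep.sum() < 2:
            raise np.linalg.LinAlgError("rank-deficient data")
        u, s = u[:, keep], s[keep]
        whitener = (u / s).T * np.sqrt(x.shape[1])      # (n_comp, n_ch)
        white = whitener @ x
        unmix = infomax(white.T, random_state=seed, verbose="error")
        sources = unmix @ white
        mixing = np.linalg.pinv(unmix @ whitener)
    except np.linalg.LinAlgError as err:
        warnings.warn(f"ICA decomposition failed ({err}); data returned unmodified")
        out = replace(rec, meta={**rec.meta, "ica_failed": True, "ica_removed": 0})
        return out

    corr = np.array([np.corrcoef(srcrow, composite)[0, 1] for srcrow in sources])
    reject = np.abs(corr) > corr_threshold
    sources[reject] = 0.0
    clean = mixing @ sources + rec.data.mean(axis=1, keepdims=True)
    return replace(rec, data=clean,
                   meta={**rec.meta, "ica_removed": int(reject.sum()), "ica_failed": False})


def epoch_and_baseline(rec: EEGRecording, onsets, duration_s: float,
                       baseline_s: float = 0.5) -> list[np.ndarray]:
    """Cut epochs and subtract the per-channel pre-onset baseline mean.

    Each epoch spans ``[onset, onset + duration_s)``; the baseline is the
    ``baseline_s`` window immediately preceding the onset.
    """
    n_base = int(round(baseline_s * rec.fs))
    n_len = int(round(duration_s * rec.fs))
    epochs = []
    for onset in onsets:
        onset = int(onset)
        if onset < n_base:
            raise ValueError(
                f"onset {onset} closer to recording start than the "
                f"{baseline_s * 1e3:.0f} ms baseline window")
        if onset + n_len > rec.n_samples:
            raise ValueError("epoch extends past the end of the recording")
        base = rec.data[:, onset - n_base:onset].mean(axis=1, keepdims=True)
        epochs.append(rec.data[:, onset:onset + n_len] - base)
    return epochs


def _cwt_power(data: np.ndarray, fs: float, freqs: np.ndarray,
               wavelet: str = "cmor1.5-1.0") -> np.ndarray:
    """Squared-magnitude CWT, (channels, freqs, samples)."""
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coeffs, _ = pywt.cwt(data, scales, wavelet, axis=-1)
    # pywt returns (scales, channels, samples)
    return np.abs(np.moveaxis(coeffs, 0, 1)) ** 2


def wavelet_band_power(rec: EEGRecording, frame_hop: float = 0.1,
                       n_freqs: int = 40) -> BandPower:
    """Morlet-CWT band power per channel, band and frame.

    Centre frequencies tile 0.5-48 Hz logarithmically; squared magnitudes
    are averaged within each canonical band and within non-overlapping
    frames of ``frame_hop`` seconds.
    """
    freqs = np.geomspace(0.5, 48.0, n_freqs)
    hop = max(1, int(round(frame_hop * rec.fs)))
    if rec.n_samples < hop:
        raise ValueError("recording shorter than one analysis frame")
    power = _cwt_power(rec.data, rec.fs, freqs)
    n_frames = rec.n_samples // hop
    power = power[:, :, :n_frames * hop].reshape(rec.n_channels, len(freqs), n_frames, hop)
    power = power.mean(axis=3)
    out = np.empty((rec.n_channels, len(BAND_ORDER), n_frames))
    for b, name in enumerate(BAND_ORDER):
        lo, hi = BANDS[name]
        sel = (freqs >= lo) & (freqs < hi)
        out[:, b, :] = power[:, sel, :].mean(axis=1)
    return BandPower(out, BAND_ORDER, hop / rec.fs)


def ersp(epochs, fs: float, baseline_power: np.ndarray,
         freqs: np.ndarray | None = None, frame_hop: float = 0.1) -> np.ndarray:
    """Event-related spectral perturbation, dB relative to baseline.

    ``epochs`` is a sequence of (channels x samples) arrays;
    ``baseline_power`` holds per-frequency baseline power (frequencies,)
    or (channels, frequencies).  Returns 10*log10(P/P_base) averaged over
    epochs and channels, shape (frequencies, frames).
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    if freqs is None:
        freqs = np.geomspace(0.5, 48.0, 40)
    baseline_power = np.asarray(baseline_power, dtype=float)
    if np.any(baseline_power <= 0):
        raise ValueError("baseline power must be positive at every frequency")
    hop = max(1, int(round(frame_hop * fs)))
    acc = None
    for ep in epochs:
        p = _cwt_power(np.atleast_2d(ep), fs, freqs)
        n_frames = p.shape[2] // hop
        p = p[:, :, :n_frames * hop].reshape(p.shape[0], len(freqs), n_frames, hop).mean(axis=3)
        if baseline_power.ndim == 1:
            rel = p / baseline_power[None, :, None]
        else:
            rel = p / baseline_power[:, :, None]
        acc = rel if acc is None else acc + rel
    return 10.0 * np.log10(acc.mean(axis=0) / len(epochs))
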