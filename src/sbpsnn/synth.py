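"""Synthetic labelled emotional EEG with controllable statistical structure.

The generator emulates the kind of recording the decoding analysis
assumes: 1/f ("pink") background activity per channel, class-conditional
band-power elevation on designated electrode subsets (beta over parietal
sites for the negative emotions, alpha modulation over frontal-central /
frontal-temporal sites for happiness), directed VAR coupling between
chosen channel pairs, and stereotyped blink artifacts on the prefrontal
row.  All randomness derives from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from sbpsnn.montage import Montage, standard_montage_62
from sbpsnn.preprocess import BANDS, EEGRecording

CLASSES = ("fear", "sad", "happy", "neutral")

_PARIETAL = ("P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8")
_FRONTO_CENTRAL = ("FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8")

#: Default class-conditional effects: (electrodes, band, power multiplier).
#: Beta elevation on parietal channels marks the negative emotions; alpha
#: modulation on frontal-central/temporal channels marks happiness.
DEFAULT_EFFECT_MAP: dict[str, list[tuple[tuple[str, ...], str, float]]] = {
    "fear": [(_PARIETAL, "beta", 2.0)],
    "sad": [(_PARIETAL, "beta", 1.8)],
    "happy": [(_FRONTO_CENTRAL, "alpha", 2.0)],
    "neutral": [],
}

#: Default directed couplings (source, sink, per-lag coefficients),
#: echoing the parietal beta projections and the frontal-central hub the
#: connectivity analysis looks for.
DEFAULT_COUPLING: list[tuple[str, str, tuple[float, ...]]] = [
    ("P1", "P2", (0.35,)),
    ("P1", "P5", (0.35,)),
    ("FC2", "FC1", (0.35,)),
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic recordings."""

    n_subjects: int = 2
    n_trials_per_class: int = 6
    classes: tuple[str, ...] = CLASSES
    fs: float = 250.0
    duration_s: float = 20.0
    effect_map: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_EFFECT_MAP.items()})
    coupling: list = field(default_factory=lambda: list(DEFAULT_COUPLING))
    artifact_rate: float = 8.0          # blinks per minute
    noise_exponent: float = 1.0         # 1/f^a background slope
    background_rms: float = 10.0        # microvolt
    blink_amplitude: float = 80.0       # microvolt at Fp1/Fp2
    baseline_s: float = 0.5             # pre-onset lead-in per trial
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 2 * 48.0:
            raise ValueError("sampling rate must exceed twice the 48 Hz band edge")
        if self.n_trials_per_class < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")
        for cls, effects in self.effect_map.items():
            if cls not in self.classes:
                continue        # default effect map covers all four classes
            for electrodes, band, mult in effects:
                if len(electrodes) == 0:
                    raise ValueError("empty electrode set in effect_map")
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r}")
                if mult <= 0:
                    raise ValueError("power multipliers must be positive")
        if self.duration_s <= 0 or self.baseline_s < 0:
            raise ValueError("durations must be positive")


@dataclass
class LabeledEEGSet:
    """Per-trial recordings with class labels and the shared montage."""

    recordings: list[EEGRecording]
    labels: list[str]
    montage: Montage

    def __post_init__(self) -> None:
        if len(self.recordings) != len(self.labels):
            raise ValueError("one label per recording required")
        if self.recordings:
            fs = self.recordings[0].fs
            chans = self.recordings[0].labels
            for rec in self.recordings:
                if rec.fs != fs or rec.labels != chans:
                    raise ValueError("recordings must share fs and channel order")

    def __len__(self) -> int:
        return len(self.recordings)

    def pick(self, electrodes) -> "LabeledEEGSet":
        recs = [rec.pick(electrodes) for rec in self.recordings]
        return LabeledEEGSet(recs, list(self.labels), self.montage.subset(electrodes))

    def subset_classes(self, classes) -> "LabeledEEGSet":
        keep = [i for i, lbl in enumerate(self.labels) if lbl in classes]
        return LabeledEEGSet([self.recordings[i] for i in keep],
                             [self.labels[i] for i in keep], self.montage)


def pink_noise(n_channels: int, n_samples: int, exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return shaped


def _band_limited_noise(band: tuple[float, float], n_samples: int, fs: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise band-passed to ``band`` (order-6 Butterworth,
    steep skirts keep the injected power inside the nominal band)."""
    lo, hi = band
    sos = signal.butter(6, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples * 2))[n_samples // 2:
                                                                    n_samples // 2 + n_samples]
    return x / x.std()


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    nper = min(len(x), int(4 * fs))
    f, p = signal.welch(x, fs=fs, nperseg=nper)
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[sel], f[sel]))


def _blink_kernel(fs: float) -> np.ndarray:
    """Stereotyped 300 ms biphasic blink pulse, unit peak."""
    t = np.arange(int(0.3 * fs)) / fs
    k = np.sin(2 * np.pi * t / 0.3) * np.exp(-((t - 0.1) / 0.12) ** 2)
    return k / np.abs(k).max()


def generate_emotion_eeg(cfg: SynthConfig, montage: Montage | None = None) -> LabeledEEGSet:
    """Generate the labelled synthetic EEG set described by ``cfg``.

    Each trial is one :class:`EEGRecording` with a ``baseline_s`` lead-in
    before the stimulus onset event; class effects (band-limited additive
    oscillations scaled to the configured power multiplier), VAR
    couplings and blink artifacts apply after the onset.  Deterministic
    given ``cfg.seed``.
    """
    cfg.validate()
    if montage is None:
        montage = standard_montage_62()
    rng = np.random.default_rng(cfg.seed)
    n_lead = int(round(cfg.baseline_s * cfg.fs))
    n_trial = int(round(cfg.duration_s * cfg.fs))
    n_total = n_lead + n_trial

    fp_idx = [i for i, lbl in enumerate(montage.labels) if lbl.startswith("Fp")]
    blink_decay_mm = 40.0
    if fp_idx:
        fp_pos = montage.coords[fp_idx].mean(axis=0)
        dists = np.linalg.norm(montage.coords - fp_pos, axis=1)
        blink_profile = np.exp(-dists / blink_decay_mm)
    kernel = _blink_kernel(cfg.fs)

    recordings: list[EEGRecording] = []
    labels: list[str] = []
    for _subj in range(cfg.n_subjects):
        order = [cls for cls in cfg.classes for _ in range(cfg.n_trials_per_class)]
        rng.shuffle(order)
        for cls in order:
            data = cfg.background_rms * pink_noise(len(montage), n_total,
                                                   cfg.noise_exponent, rng)
            events: list[tuple[int, str]] = [(n_lead, "stim")]
            # class-conditional band-power elevation (additive oscillation)
            for electrodes, band, mult in cfg.effect_map.get(cls, []):
                for lbl in electrodes:
                    ch = montage.index(lbl)
                    p_bg = _band_power(data[ch, n_lead:], cfg.fs, BANDS[band])
                    add_var = max(mult - 1.0, 0.0) * p_bg
                    if add_var > 0:
                        osc = _band_limited_noise(BANDS[band], n_trial, cfg.fs, rng)
                        data[ch, n_lead:] += np.sqrt(add_var) * osc
            # directed VAR coupling: sink receives lagged source signal
            for src, snk, coeffs in cfg.coupling:
                si, ki = montage.index(src), montage.index(snk)
                for lag, a in enumerate(coeffs, start=1):
                    data[ki, n_lead + lag:] += a * data[si, n_lead:-lag]
            # blink artifacts on the prefrontal row
            if fp_idx and cfg.artifact_rate > 0:
                n_blinks = rng.poisson(cfg.artifact_rate * cfg.duration_s / 60.0)
                starts = rng.integers(0, max(1, n_trial - len(kernel)), size=n_blinks)
                for s in np.sort(starts):
                    seg = slice(n_lead + s, n_lead + s + len(kernel))
                    amp = cfg.blink_amplitude * (0.8 + 0.4 * rng.random())
                    data[:, seg] += amp * np.outer(blink_profile, kernel)
                    events.append((n_lead + int(s), "blink"))
            recordings.append(EEGRecording(data, cfg.fs, montage.labels, events))
            labels.append(cls)
    return LabeledEEGSet(recordings, labels, montage)


def generate_var_pair(a, order: int = 1, n: int = 20000, seed: int = 0,
                      phi_x: float = 0.5) -> np.ndarray:
    """Two-channel VAR fixture with known directed influence x -> y.

    ``x`` is an autonomous AR(1) with coefficient ``phi_x``; ``y[t]``
    depends on ``x[t-1..t-order]`` with coefficient(s) ``a`` plus
    unit-variance white innovations.  Returns an array of shape (2, n)
    ordered (x, y).  Raises on unstable coefficient sets (companion
    matrix spectral radius >= 1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if order < 1:
        raise ValueError("order must be >= 1")
    coeffs = np.atleast_1d(np.asarray(a, dtype=float))
    if len(coeffs) == 1 and order > 1:
        coeffs = np.repeat(coeffs, order)
    if len(coeffs) != order:
        raise ValueError("need one coupling coefficient per lag")
    # companion matrix of the joint VAR(order)
    p, k = order, 2
    A = np.zeros((p, k, k))
    A[0, 0, 0] = phi_x
    for lag in range(p):
        A[lag, 1, 0] = coeffs[lag]
    comp = np.zeros((k * p, k * p))
    comp[:k, :] = np.concatenate(A, axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    if np.max(np.abs(np.linalg.eigvals(comp))) >= 1.0:
        raise ValueError("unstable VAR: companion spectral radius >= 1")
    if np.max(np.abs(coeffs)) >= 1.0 or abs(phi_x) >= 1.0:
        raise ValueError("coefficients must have magnitude < 1")

    rng = np.random.default_rng(seed)
    burn = 10 * order + 100
    e = rng.standard_normal((2, n + burn))
    x = np.zeros(n + burn)
    y = np.zeros(n + burn)
    for t in range(1, n + burn):
        x[t] = phi_x * x[t - 1] + e[0, t]
        acc = 0.0
        for lag in range(1, min(order, t) + 1):
            acc += coeffs[lag - 1] * x[t - lag]
        y[t] = acc + e[1, t]
    return np.vstack([x, y])[:, burn:]


def write_dataset(dataset: LabeledEEGSet, outdir, trials_per_subject: int | None = None) -> None:
    """Write the set as plain text: per-subject data TSVs, labels TSV, montage TSV.

    Each recording becomes one ``subject{S}_trial{T}.tsv`` matrix
    (channels as columns, header row of labels); ``labels.tsv`` maps
    (file, onset_sample, class).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.montage.to_tsv(outdir / "montage.tsv")
    if dataset.recordings:
        (outdir / "meta.tsv").write_text(f"fs\t{dataset.recordings[0].fs}\n")
    n = len(dataset)
    per = trials_per_subject or n
    lines = ["file\tonset\tclass"]
    for i, (rec, lbl) in enumerate(zip(dataset.recordings, dataset.labels)):
        subj, trial = divmod(i, per)
        name = f"subject{subj}_trial{trial}.tsv"
        header = "\t".join(rec.labels)
        body = "\n".join("\t".join(f"{v:.4f}" for v in row) for row in rec.data.T)
        (outdir / name).write_text(f"{header}\n{body}\n")
        onset = next((s for s, code in rec.events if code == "stim"), 0)
        lines.append(f"{name}\t{onset}\t{lbl}")
    (outdir / "labels.tsv").write_text("\n".join(lines) + "\n")


def read_dataset(indir) -> LabeledEEGSet:
    """Read a dataset written by :func:`write_dataset` (fs from meta.tsv or 250)."""
    indir = Path(indir)
    montage = Montage.from_tsv(indir / "montage.tsv")
    meta = indir / "meta.tsv"
    fs = float(meta.read_text().split()[1]) if meta.exists() else 250.0
    recs, labels = [], []
    for ln in (indir / "labels.tsv").read_text().strip().splitlines()[1:]:
        name, onset, cls = ln.split("\t")
        rows = (indir / name).read_text().strip().splitlines()
        chans = tuple(rows[0].split("\t"))
        data = np.array([[float(v) for v in r.split("\t")] for r in rows[1:]]).T
        recs.append(EEGRecording(data, fs, chans, [(int(onset), "stim")]))
        labels.append(cls)
    return LabeledEEGSet(recs, labels, montage)
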