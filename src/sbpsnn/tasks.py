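"""Standard desk-scale decoding tasks and multi-seed experiments.

These builders freeze the study conditions used throughout the test
suite: the trivially separable spike fixture, and the standard synthetic
emotion task (binary emotion-vs-neutral, band-limited power elevation on
a designated electrode subset over pink-noise background).  The
experiment runners wrap them into the multi-seed comparisons the
analysis reports: SBP on/off ablation, planted-subset mining recovery,
and per-band biomarker attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sbpsnn.encode import SpikeTensor, encode_threshold
from sbpsnn.evaluation import evaluate, stratified_split
from sbpsnn.montage import standard_montage_62
from sbpsnn.preprocess import bandpass, rereference_average
from sbpsnn.snn import EmotionDecoder, TrainConfig
from sbpsnn.synth import LabeledEEGSet, SynthConfig, generate_emotion_eeg

#: Training configuration for desk-scale experiments: reduced epochs keep
#: multi-seed comparisons tractable; the 40 Hz teaching rate places the
#: target spike count inside the LIF dynamic range at these time steps.
STANDARD_TRAIN = dict(epochs=60, batch_size=20, teaching_rate=40.0)
SEPARABLE_TRAIN = dict(epochs=100, batch_size=20, teaching_rate=40.0)


def make_separable_task(n_per_class: int = 20, n_steps: int = 300,
                        dt: float = 0.002, background_rate: float = 0.01,
                        drive_rate: float = 0.2, seed: int = 0):
    """Trivially separable fixture: input neuron 0 fires only for class 'emo'.

    All 100 input neurons carry sparse background spikes; neuron 0
    additionally fires at ``drive_rate`` per step during 'emo' trials and
    is silent otherwise.
    """
    rng = np.random.default_rng(seed)
    neuron_map = tuple((f"n{i}", "on") for i in range(100))
    tensors, labels = [], []
    for cls in ("emo", "neutral"):
        for _ in range(n_per_class):
            spk = (rng.random((100, n_steps)) < background_rate).astype(np.uint8)
            if cls == "emo":
                spk[0] = (rng.random(n_steps) < drive_rate).astype(np.uint8)
            else:
                spk[0] = 0
            tensors.append(SpikeTensor(spk, dt, neuron_map))
            labels.append(cls)
    return tensors, labels


@dataclass
class EmotionTask:
    """Encoded emotion task: per-trial spike tensors plus bookkeeping."""

    tensors: list
    labels: list
    electrodes: tuple
    montage: object
    dataset: LabeledEEGSet
    train_idx: np.ndarray = field(default=None)
    test_idx: np.ndarray = field(default=None)

    def split(self):
        tr, te = self.train_idx, self.test_idx
        return ([self.tensors[i] for i in tr], [self.labels[i] for i in tr],
                [self.tensors[i] for i in te], [self.labels[i] for i in te])


def encode_dataset(dataset: LabeledEEGSet, electrodes, k: float = 0.5):
    """Band-pass, re-reference and threshold-encode every trial.

    The encoding threshold is calibrated per channel on the pooled trials
    (k times the pooled SD of the first difference) so that amplitude
    differences between trials survive as rate differences.
    """
    recs = [rereference_average(bandpass(rec)) for rec in dataset.recordings]
    picked = [rec.pick(electrodes) for rec in recs]
    pooled = np.concatenate([np.diff(rec.data, axis=1) for rec in picked], axis=1)
    theta = k * pooled.std(axis=1)
    return [encode_threshold(rec.data, dt=1.0 / rec.fs, labels=electrodes,
                             theta=theta) for rec in picked]


def make_emotion_task(signal_electrodes=("P1", "P2"),
                      context_electrodes=("P1", "P2", "P3", "P4", "Pz"),
                      emotion: str = "fear", band: str = "beta",
                      multiplier: float = 3.0, n_per_class: int = 32,
                      fs: float = 128.0, duration_s: float = 1.5,
                      seed: int = 0, test_fraction: float = 0.25) -> EmotionTask:
    """Binary emotion-vs-neutral task with a planted band effect.

    The configured band's power is multiplied on ``signal_electrodes``
    during emotion trials; ``context_electrodes`` (a superset) are the
    channels offered to the decoder.
    """
    montage = standard_montage_62()
    cfg = SynthConfig(
        n_subjects=1, n_trials_per_class=n_per_class,
        classes=(emotion, "neutral"), fs=fs, duration_s=duration_s,
        effect_map={emotion: [(tuple(signal_electrodes), band, multiplier)],
                    "neutral": []},
        coupling=[], artifact_rate=0.0, baseline_s=0.0, seed=seed)
    dataset = generate_emotion_eeg(cfg, montage)
    tensors = encode_dataset(dataset, tuple(context_electrodes))
    tr, te = stratified_split(dataset.labels, test_fraction, seed=seed)
    return EmotionTask(tensors, list(dataset.labels), tuple(context_electrodes),
                       montage, dataset, tr, te)


def fit_and_score(task: EmotionTask, seed: int = 0, sbp_enabled: bool = True,
                  epochs: int | None = None, **model_kwargs):
    """Train on the task's train split, return the test-set EvalReport."""
    tr_x, tr_y, te_x, te_y = task.split()
    model_kwargs.setdefault("w_decay", 0.1)
    model = EmotionDecoder(tr_x, tr_y, electrodes=task.electrodes,
                           montage=task.montage, sbp_enabled=sbp_enabled,
                           **model_kwargs)
    cfg_kwargs = dict(STANDARD_TRAIN)
    if epochs is not None:
        cfg_kwargs["epochs"] = epochs
    fit = model.fit(TrainConfig(seed=seed, **cfg_kwargs))
    preds = fit.predict(te_x)
    return evaluate(preds, te_y, task="binary"), fit


def sbp_ablation_experiment(n_seeds: int = 20, base_seed: int = 0):
    """Paired test accuracies with SBP on vs off over seeded replicates.

    Returns (acc_on, acc_off) arrays in percent, one entry per seed; the
    data, the initialisation and the training schedule are matched within
    each pair.
    """
    acc_on, acc_off = [], []
    for s in range(n_seeds):
        task = make_emotion_task(seed=base_seed + 1000 + s)
        rep_on, _ = fit_and_score(task, seed=base_seed + s, sbp_enabled=True)
        rep_off, _ = fit_and_score(task, seed=base_seed + s, sbp_enabled=False)
        acc_on.append(rep_on.accuracy)
        acc_off.append(rep_off.accuracy)
    return np.array(acc_on), np.array(acc_off)


def mining_survival_experiment(n_runs: int = 20, base_seed: int = 0,
                               signal=("P1", "P2"),
                               context=("P1", "P2", "P3", "P4", "Pz"),
                               epochs: int = 45):
    """Planted-subset recovery: how often both signal electrodes survive.

    Mines a 5-electrode parietal subnetwork with the class effect planted
    on two electrodes and reports the fraction of runs in which both
    planted electrodes are still present in the final 2-electrode step.
    """
    from sbpsnn.mining import SubnetworkDef, mine_subnetwork

    survived = 0
    traces = []
    for r in range(n_runs):
        task = make_emotion_task(signal_electrodes=signal,
                                 context_electrodes=context,
                                 seed=base_seed + 2000 + r)
        subnet = SubnetworkDef(6, tuple(context))
        cfg_kwargs = dict(STANDARD_TRAIN)
        cfg_kwargs["epochs"] = epochs
        trace = mine_subnetwork(task.tensors, task.labels, subnet,
                                task.train_idx, task.test_idx, task.montage,
                                cfg=TrainConfig(seed=base_seed + r, **cfg_kwargs),
                                stop_at_size=2, w_decay=0.1)
        pair_steps = [st for st in trace.steps if len(st.electrodes) == 2]
        if pair_steps and set(signal) == set(pair_steps[0].electrodes):
            survived += 1
        traces.append(trace)
    return survived / n_runs, traces


def band_biomarker_experiment(n_runs: int = 20, base_seed: int = 0,
                              epochs: int = 30, n_folds: int = 2):
    """Planted-beta recovery by per-band decoding and EasyMKL attribution.

    Per-band accuracy is the ``n_folds``-fold cross-validated mean (every
    trial evaluated once, independent trainings per fold), which tightens
    the arg-max comparison.  Returns (decode_hits, mkl_hits, n_runs,
    mkl_sums): counts of runs in which beta is the arg-max band for each
    method, plus the MKL contribution sums (always 100 up to rounding).
    """
    from sbpsnn.biomarker import (band_decode_all, band_feature_blocks,
                                  easymkl_contributions)
    from sbpsnn.preprocess import BAND_ORDER

    decode_hits = mkl_hits = 0
    mkl_sums = []
    for r in range(n_runs):
        task = make_emotion_task(seed=base_seed + 3000 + r, n_per_class=32)
        labels = np.asarray(task.labels)
        accs = {b: 0.0 for b in BAND_ORDER}
        for fold in range(n_folds):
            rng = np.random.default_rng(base_seed + 7000 + r)
            order = np.concatenate([rng.permutation(np.flatnonzero(labels == c))
                                    for c in sorted(set(task.labels))])
            test_idx = np.sort(order[fold::n_folds])
            train_idx = np.sort(np.setdiff1d(np.arange(len(labels)), test_idx))
            res = band_decode_all(task.dataset, task.labels, task.electrodes,
                                  train_idx, test_idx, task.montage,
                                  cfg=TrainConfig(seed=base_seed + r * n_folds + fold,
                                                  epochs=epochs, batch_size=20,
                                                  teaching_rate=40.0),
                                  w_decay=0.02)
            for b, (a, _f) in res.items():
                accs[b] += a / n_folds
        decode_hits += max(accs, key=accs.get) == "beta"
        blocks = band_feature_blocks(task.dataset, task.labels,
                                     task.electrodes)
        contribs = easymkl_contributions(blocks, task.labels)
        mkl_hits += max(contribs, key=contribs.get) == "beta"
        mkl_sums.append(sum(contribs.values()))
    return decode_hits, mkl_hits, n_runs, mkl_sums


def granger_direction_experiment(n: int = 20000, seed: int = 0):
    """Directed-pair and null GC levels on the VAR fixtures."""
    from sbpsnn.connectivity import spectral_granger
    from sbpsnn.synth import generate_var_pair

    xy = generate_var_pair(0.5, order=1, n=n, seed=seed)
    gc = spectral_granger(xy, fs=100.0, order=20)
    fwd = float(gc.pair("ch0", "ch1").mean())
    rev = float(gc.pair("ch1", "ch0").mean())
    null = generate_var_pair(0.0, order=1, n=n, seed=seed + 1)
    g0 = spectral_granger(null, fs=100.0, order=20)
    null_max = float(max(g0.pair("ch0", "ch1").mean(),
                         g0.pair("ch1", "ch0").mean()))
    return fwd, rev, null_max


def chain_recovery_experiment(n_runs: int = 10, base_seed: int = 0,
                              n_trials: int = 6, n: int = 3000):
    """x->y->z chain: fraction of runs recovering both true edges and
    rejecting the reverse z->x edge."""
    from sbpsnn.connectivity import directed_network

    hits = 0
    for r in range(n_runs):
        rng = np.random.default_rng(base_seed + 4000 + r)
        trials = []
        for _t in range(n_trials):
            e = rng.standard_normal((3, n))
            x = np.zeros(n); y = np.zeros(n); z = np.zeros(n)
            for t in range(1, n):
                x[t] = 0.5 * x[t - 1] + e[0, t]
                y[t] = 0.5 * x[t - 1] + e[1, t]
                z[t] = 0.5 * y[t - 1] + e[2, t]
            trials.append(np.vstack([x, y, z]))
        net = directed_network(trials, fs=100.0, electrodes=("x", "y", "z"),
                               band=(1.0, 48.0), order=5, n_surrogates=10,
                               seed=base_seed + r)
        found = {(s, d) for s, d, _b, _v in net.edges}
        hits += (("x", "y") in found and ("y", "z") in found
                 and ("z", "x") not in found)
    return hits, n_runs
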