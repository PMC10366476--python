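"""Electrode-subnetwork mining by contribution-ranked elimination.

The scalp montage is partitioned into seven subnetworks by 10-20 label
prefix (1: Fp+AF, 2: F, 3: FC+FT, 4: C+T, 5: CP+TP, 6: P, 7: PO+O).
Within a subnetwork, a decoder is trained on the current electrode set,
per-electrode contributions are computed, and the lowest-contributing
electrode is eliminated; iterating until a single electrode remains (or
performance stays poor) yields a trace of models from which the best and
the simplest are selected.

Three contribution readings are provided (the metric itself is a design
choice): ``occlusion`` (default) scores each electrode by the drop in
class separation of the trained decoder's output counts when that
electrode's input streams are silenced; ``weight`` uses input-weight
mass sum(|W_ij|); ``drop_one`` retrains without the electrode and scores
the accuracy drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sbpsnn.encode import project_spikes
from sbpsnn.evaluation import evaluate
from sbpsnn.montage import Montage
from sbpsnn.snn import DecoderFit, EmotionDecoder, TrainConfig

#: Subnetwork id -> 10-20 row prefixes, longest prefix matched first.
SUBNETWORK_PREFIXES: dict[int, tuple[str, ...]] = {
    1: ("Fp", "AF"),
    2: ("F",),
    3: ("FC", "FT"),
    4: ("C", "T"),
    5: ("CP", "TP"),
    6: ("P",),
    7: ("PO", "O"),
}


@dataclass(frozen=True)
class SubnetworkDef:
    id: int
    electrodes: tuple[str, ...]


@dataclass(frozen=True)
class ModelPerformance:
    accuracy: float             # percent
    f1: float

    def __post_init__(self) -> None:
        if not (0 <= self.accuracy <= 100 and 0 <= self.f1 <= 1):
            raise ValueError("accuracy must be in [0,100], f1 in [0,1]")


@dataclass(frozen=True)
class MiningStep:
    electrodes: tuple[str, ...]
    contributions: dict[str, float]      # percent, sums to 100
    eliminated: str | None
    performance: ModelPerformance


@dataclass
class MiningTrace:
    subnetwork: SubnetworkDef
    steps: list[MiningStep] = field(default_factory=list)

    @property
    def best_index(self) -> int:
        return self.select()[0]

    @property
    def simplest_index(self) -> int:
        return len(self.steps) - 1

    def select(self) -> tuple[int, int]:
        """(best step index, simplest step index).

        Best = highest accuracy; ties broken by higher F1, then by fewer
        electrodes.  Simplest = the final recorded step.
        """
        if not self.steps:
            raise ValueError("empty mining trace")
        best = 0
        for i, st in enumerate(self.steps[1:], start=1):
            b = self.steps[best]
            key_new = (st.performance.accuracy, st.performance.f1,
                       -len(st.electrodes))
            key_old = (b.performance.accuracy, b.performance.f1,
                       -len(b.electrodes))
            if key_new > key_old:
                best = i
        return best, len(self.steps) - 1


def partition_subnetworks(montage: Montage) -> list[SubnetworkDef]:
    """Assign every electrode to one of the seven scalp subnetworks.

    Longest-prefix matching on the 10-20 label (so FC goes to the
    frontal-central group 3, not the frontal group 2); unrecognised
    labels raise.
    """
    ordered = sorted(((p, sid) for sid, ps in SUBNETWORK_PREFIXES.items()
                      for p in ps), key=lambda t: -len(t[0]))
    groups: dict[int, list[str]] = {sid: [] for sid in SUBNETWORK_PREFIXES}
    for lbl in montage.labels:
        for prefix, sid in ordered:
            if lbl.startswith(prefix):
                groups[sid].append(lbl)
                break
        else:
            raise ValueError(f"electrode label {lbl!r} matches no subnetwork prefix")
    return [SubnetworkDef(sid, tuple(groups[sid])) for sid in sorted(groups)]


def electrode_contribution(fit: DecoderFit, electrodes=None) -> dict[str, float]:
    """Input-weight-mass contributions in percent (sums to 100).

    contribution_e = sum over e's input neurons and all hidden neurons of
    |W_ij|, normalised across electrodes.
    """
    mass = fit.electrode_weight_mass()
    if electrodes is not None:
        missing = set(electrodes) - set(mass)
        if missing:
            raise KeyError(f"electrodes absent from the input map: {sorted(missing)}")
        mass = {e: mass[e] for e in electrodes}
    total = sum(mass.values())
    if total <= 0:
        return {e: 100.0 / len(mass) for e in mass}
    return {e: 100.0 * v / total for e, v in mass.items()}


def occlusion_contribution(fit: DecoderFit, spike_tensors, labels) -> dict[str, float]:
    """Contribution via single-electrode occlusion of the trained decoder.

    Each electrode's input streams are silenced in turn and the reduction
    in the output-count class separation (binary) or in the mean margin
    of the true-class output (multi-class) is recorded; reductions are
    clipped at zero and normalised to percent.
    """
    m = fit.model
    proj = np.stack([_pad(project_spikes(st, m.input_streams),
                          max(s.n_steps for s in spike_tensors))
                     for st in spike_tensors])
    label_idx = np.array([m.classes.index(l) for l in labels])

    def separation(p):
        _, out, _, _, _ = m._simulate_batch(p, fit.w_in, fit.w_out,
                                            fit.v_th_hidden, None)
        if m.n_out == 1:
            return out[label_idx == 1, 0].mean() - out[label_idx == 0, 0].mean()
        margins = [out[b, li] - np.delete(out[b], li).max()
                   for b, li in enumerate(label_idx)]
        return float(np.mean(margins))

    base = separation(proj)
    electrodes = sorted({e for e, _pol in m.input_streams})
    scores = {}
    for e in electrodes:
        rows = [i for i, (el, _pol) in enumerate(m.input_streams) if el == e]
        masked = proj.copy()
        masked[:, rows, :] = 0
        scores[e] = max(base - separation(masked), 0.0)
    total = sum(scores.values())
    if total <= 0:
        return {e: 100.0 / len(scores) for e in scores}
    return {e: 100.0 * v / total for e, v in scores.items()}


def _pad(arr: np.ndarray, n_steps: int) -> np.ndarray:
    if arr.shape[1] == n_steps:
        return arr
    out = np.zeros((arr.shape[0], n_steps), dtype=arr.dtype)
    out[:, :arr.shape[1]] = arr
    return out


def mine_subnetwork(spike_tensors, labels, subnet: SubnetworkDef,
                    train_idx, test_idx, montage: Montage,
                    cfg: TrainConfig | None = None,
                    contribution: str = "occlusion",
                    early_stop_margin: float = 5.0,
                    early_stop_patience: int = 3,
                    stop_at_size: int = 1,
                    **model_kwargs) -> MiningTrace:
    """Iterative elimination over one subnetwork's electrodes.

    ``spike_tensors`` must carry ON/OFF streams for every subnetwork
    electrode.  At each step a fresh decoder is trained on the current
    electrode set (no warm start), evaluated on the held-out split, and
    the lowest-contributing electrode is eliminated (ties broken
    alphabetically).  Stops after one electrode remains, or early when
    accuracy stays below chance + ``early_stop_margin`` points for
    ``early_stop_patience`` consecutive steps.
    """
    if not subnet.electrodes:
        raise ValueError("empty subnetwork")
    if contribution not in ("occlusion", "weight", "drop_one"):
        raise ValueError(f"unknown contribution mode {contribution!r}")
    cfg = cfg or TrainConfig()
    current = list(subnet.electrodes)
    trace = MiningTrace(subnet)
    poor_streak = 0

    def run(electrodes, seed_shift=0):
        tr_x = [spike_tensors[i] for i in train_idx]
        tr_y = [labels[i] for i in train_idx]
        te_x = [spike_tensors[i] for i in test_idx]
        te_y = [labels[i] for i in test_idx]
        model = EmotionDecoder(tr_x, tr_y, electrodes=tuple(electrodes),
                               montage=montage, **model_kwargs)
        fit = model.fit(TrainConfig(cfg.epochs, cfg.batch_size,
                                    cfg.teaching_rate, cfg.seed + seed_shift))
        rep = evaluate(fit.predict(te_x), te_y,
                       task="binary" if len(model.classes) == 2 else "four_class")
        return fit, rep, tr_x, tr_y

    while True:
        fit, rep, tr_x, tr_y = run(current)
        if contribution == "weight":
            contribs = electrode_contribution(fit, current)
        elif contribution == "occlusion":
            contribs = occlusion_contribution(fit, tr_x, tr_y)
        else:   # drop_one: retrain without each electrode
            contribs = {}
            for e in current:
                if len(current) == 1:
                    contribs[e] = 100.0
                    break
                rest = [x for x in current if x != e]
                _, rep_e, _, _ = run(rest, seed_shift=1 + current.index(e))
                contribs[e] = max(rep.accuracy - rep_e.accuracy, 0.0)
            total = sum(contribs.values())
            contribs = ({e: 100.0 / len(contribs) for e in contribs} if total <= 0
                        else {e: 100.0 * v / total for e, v in contribs.items()})

        if len(current) <= max(1, stop_at_size):
            trace.steps.append(MiningStep(tuple(current), contribs, None,
                                          ModelPerformance(rep.accuracy, rep.f1)))
            break
        victim = min(sorted(current), key=lambda e: contribs[e])
        trace.steps.append(MiningStep(tuple(current), contribs, victim,
                                      ModelPerformance(rep.accuracy, rep.f1)))
        poor_streak = poor_streak + 1 if rep.accuracy < rep.chance_level + \
            early_stop_margin else 0
        if poor_streak >= early_stop_patience:
            break
        current.remove(victim)
    return trace


def select_best_simplest(trace: MiningTrace) -> tuple[MiningStep, MiningStep]:
    """The best-performing and the simplest (final) model of a trace."""
    b, s = trace.select()
    return trace.steps[b], trace.steps[s]


def trace_to_rows(trace: MiningTrace) -> list[dict]:
    """Flatten a trace for CSV serialisation."""
    import json
    rows = []
    for i, st in enumerate(trace.steps):
        rows.append({
            "subnetwork": trace.subnetwork.id,
            "step": i,
            "electrodes": "+".join(st.electrodes),
            "eliminated": st.eliminated or "",
            "contributions": json.dumps({k: round(v, 3)
                                         for k, v in st.contributions.items()}),
            "accuracy": st.performance.accuracy,
            "f1": st.performance.f1,
        })
    return rows
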