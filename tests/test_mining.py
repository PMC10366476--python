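import numpy as np
import pytest

from sbpsnn.mining import (MiningStep, MiningTrace, ModelPerformance,
                           SubnetworkDef, electrode_contribution,
                           mine_subnetwork, partition_subnetworks,
                           select_best_simplest)
from sbpsnn.snn import TrainConfig


class TestPartition:
    @pytest.mark.parametrize("label, subnet", [
        ("Fp1", 1), ("AF3", 1), ("Fz", 2), ("F7", 2),
        ("FC1", 3), ("FT8", 3), ("Cz", 4), ("T7", 4),
        ("CP3", 5), ("TP7", 5), ("P7", 6), ("Pz", 6),
        ("PO3", 7), ("O1", 7),
    ])
    def test_prefix_rules(self, montage, label, subnet):
        subnets = {s.id: s for s in partition_subnetworks(montage)}
        assert label in subnets[subnet].electrodes

    def test_longest_prefix_wins(self, montage):
        subnets = {s.id: s for s in partition_subnetworks(montage)}
        assert "FC1" not in subnets[2].electrodes        # not plain F
        assert "CP1" not in subnets[4].electrodes        # not plain C
        assert "PO3" not in subnets[6].electrodes        # not plain P


class TestContribution:
    def _fit(self, electrodes, seed=0):
        from sbpsnn.tasks import make_emotion_task
        task = make_emotion_task(context_electrodes=electrodes,
                                 signal_electrodes=electrodes[:1],
                                 n_per_class=8, seed=seed)
        from sbpsnn.snn import EmotionDecoder
        tr_x, tr_y, _, _ = task.split()
        model = EmotionDecoder(tr_x, tr_y, electrodes=electrodes,
                               montage=task.montage)
        return model.fit(TrainConfig(epochs=3, batch_size=20,
                                     teaching_rate=40.0, seed=seed))

    def test_percentages_sum_to_100(self):
        fit = self._fit(("P1", "P2", "Pz"))
        contribs = electrode_contribution(fit)
        assert sum(contribs.values()) == pytest.approx(100.0, abs=0.1)

    def test_single_electrode_is_100(self):
        fit = self._fit(("P1",))
        contribs = electrode_contribution(fit)
        assert contribs == {"P1": pytest.approx(100.0)}

    def test_missing_electrode_rejected(self):
        fit = self._fit(("P1", "P2"))
        with pytest.raises(KeyError):
            electrode_contribution(fit, electrodes=("Oz",))


class TestTraceSelection:
    def _trace(self, perfs):
        steps = []
        n = len(perfs)
        for i, (acc, f1) in enumerate(perfs):
            elecs = tuple(f"E{j}" for j in range(n - i))
            steps.append(MiningStep(elecs, {e: 100 / len(elecs) for e in elecs},
                                    elecs[-1] if len(elecs) > 1 else None,
                                    ModelPerformance(acc, f1)))
        return MiningTrace(SubnetworkDef(1, tuple(f"E{j}" for j in range(n))),
                           steps)

    def test_accuracy_tie_broken_by_f1_then_fewer_electrodes(self):
        # two steps at accuracy 73 / F1 0.74: the later (smaller) model wins
        trace = self._trace([(59, 0.59), (73, 0.74), (70, 0.70),
                             (68, 0.70), (73, 0.74)])
        best, simplest = select_best_simplest(trace)
        assert len(best.electrodes) == 1          # the later of the two 73s
        assert simplest is trace.steps[-1]

    def test_strictly_decreasing_best_is_first(self):
        trace = self._trace([(80, 0.8), (70, 0.7), (60, 0.6)])
        best, _ = select_best_simplest(trace)
        assert best is trace.steps[0]

    def test_single_step_best_equals_simplest(self):
        trace = self._trace([(66, 0.6)])
        best, simplest = select_best_simplest(trace)
        assert best is simplest

    def test_empty_trace_rejected(self):
        trace = MiningTrace(SubnetworkDef(1, ("E0",)), [])
        with pytest.raises(ValueError, match="empty"):
            trace.select()


@pytest.fixture(scope="module")
def small_task():
    from sbpsnn.tasks import make_emotion_task
    return make_emotion_task(signal_electrodes=("P1",),
                             context_electrodes=("P1", "P2", "Pz"),
                             n_per_class=10, duration_s=1.0, seed=21)


class TestMineSubnetwork:

    def test_full_trace_ends_with_single_electrode(self, small_task):
        subnet = SubnetworkDef(6, small_task.electrodes)
        trace = mine_subnetwork(small_task.tensors, small_task.labels, subnet,
                                small_task.train_idx, small_task.test_idx,
                                small_task.montage,
                                cfg=TrainConfig(epochs=5, batch_size=20,
                                                teaching_rate=40.0, seed=0),
                                early_stop_patience=10)
        assert len(trace.steps) == 3
        sizes = [len(s.electrodes) for s in trace.steps]
        assert sizes == [3, 2, 1]
        for st in trace.steps:
            assert sum(st.contributions.values()) == pytest.approx(100.0,
                                                                   abs=0.1)
        # eliminated electrode is always the arg-min contribution
        for st in trace.steps[:-1]:
            low = min(sorted(st.electrodes), key=lambda e: st.contributions[e])
            assert st.eliminated == low

    def test_single_electrode_subnetwork(self, small_task):
        subnet = SubnetworkDef(6, ("P1",))
        trace = mine_subnetwork(small_task.tensors, small_task.labels, subnet,
                                small_task.train_idx, small_task.test_idx,
                                small_task.montage,
                                cfg=TrainConfig(epochs=3, batch_size=20,
                                                teaching_rate=40.0, seed=0))
        assert len(trace.steps) == 1
        best, simplest = select_best_simplest(trace)
        assert best is simplest

    def test_empty_subnetwork_rejected(self, small_task):
        with pytest.raises(ValueError, match="empty subnetwork"):
            mine_subnetwork(small_task.tensors, small_task.labels,
                            SubnetworkDef(6, ()), small_task.train_idx,
                            small_task.test_idx, small_task.montage)

    def test_unknown_contribution_mode_rejected(self, small_task):
        with pytest.raises(ValueError, match="contribution mode"):
            mine_subnetwork(small_task.tensors, small_task.labels,
                            SubnetworkDef(6, ("P1",)), small_task.train_idx,
                            small_task.test_idx, small_task.montage,
                            contribution="magic")
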