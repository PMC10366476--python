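"""End-to-end orchestration: simulate -> preprocess -> encode -> train ->
mine -> fuse -> bands/MKL -> Granger, with provenance-stamped artifacts.

Every stage writes CSV artifacts whose first line is a provenance comment
(config hash, seed, package version), so identical configurations yield
identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import sbpsnn
from sbpsnn.biomarker import band_decode_all, band_feature_blocks, easymkl_contributions
from sbpsnn.evaluation import evaluate, stratified_split
from sbpsnn.fusion import (PerformancePoint, build_fusion, high_cluster,
                           kmeans_2, rank_models)
from sbpsnn.mining import (MiningTrace, mine_subnetwork, partition_subnetworks,
                           select_best_simplest, trace_to_rows)
from sbpsnn.montage import standard_montage_62
from sbpsnn.preprocess import bandpass, remove_artifacts_ica, rereference_average
from sbpsnn.snn import EmotionDecoder, TrainConfig
from sbpsnn.synth import SynthConfig, generate_emotion_eeg, write_dataset
from sbpsnn.tasks import encode_dataset
from sbpsnn.connectivity import directed_network
from sbpsnn.preprocess import BANDS

log = logging.getLogger("sbpsnn")


@dataclass
class RunConfig:
    """Stage parameters for the full workflow (YAML round-trippable)."""

    out_dir: str = "run_output"
    seed: int = 0
    emotion: str = "fear"
    # simulate
    n_trials_per_class: int = 16
    fs: float = 128.0
    duration_s: float = 1.5
    effect_multiplier: float = 3.0
    signal_electrodes: tuple = ("P1", "P2")
    artifact_rate: float = 8.0
    noise_exponent: float = 1.0
    # preprocess
    run_ica: bool = True
    ica_threshold: float = 0.7
    # decoding
    epochs: int = 30
    batch_size: int = 20
    teaching_rate: float = 40.0
    test_fraction: float = 0.25
    w_decay: float = 0.1
    # mining / fusion
    mine_subnetworks: tuple = (6,)
    contribution: str = "occlusion"
    # connectivity
    gc_electrodes: tuple = ("P1", "P2", "P5")
    gc_band: str = "beta"
    gc_order: int = 8
    gc_surrogates: int = 8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for tup in ("signal_electrodes", "mine_subnetworks", "gc_electrodes"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def hash(self) -> str:
        # the output location is not a scientific parameter
        d = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig) -> str:
    return (f"# config_hash={cfg.hash()} seed={cfg.seed} "
            f"sbpsnn={sbpsnn.__version__}")


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(cfg) + "\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage in order; returns the output directory.

    Any stage failure raises with the stage name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    stage = "init"
    t0 = time.time()
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        log.info("stage=%s", stage)
        montage = standard_montage_62()
        scfg = SynthConfig(
            n_subjects=1, n_trials_per_class=cfg.n_trials_per_class,
            classes=(cfg.emotion, "neutral"), fs=cfg.fs,
            duration_s=cfg.duration_s,
            effect_map={cfg.emotion: [(tuple(cfg.signal_electrodes), "beta",
                                       cfg.effect_multiplier)],
                        "neutral": []},
            coupling=[(cfg.gc_electrodes[0], e, (0.35,))
                      for e in cfg.gc_electrodes[1:]],
            artifact_rate=cfg.artifact_rate,
            noise_exponent=cfg.noise_exponent, seed=cfg.seed)
        dataset = generate_emotion_eeg(scfg, montage)
        write_dataset(dataset, out / "simulated")

        # --- preprocess ---------------------------------------------------
        stage = "preprocess"
        log.info("stage=%s", stage)
        cleaned = []
        for rec in dataset.recordings:
            r = bandpass(rec)
            if cfg.run_ica:
                r = remove_artifacts_ica(r, corr_threshold=cfg.ica_threshold,
                                         seed=cfg.seed)
            cleaned.append(rereference_average(r))
        dataset.recordings = cleaned

        # --- encode + train on the mined subnetwork -----------------------
        stage = "encode"
        log.info("stage=%s", stage)
        subnets = {s.id: s for s in partition_subnetworks(montage)}
        electrodes = tuple(e for sid in cfg.mine_subnetworks
                           for e in subnets[sid].electrodes)
        tensors = encode_dataset(dataset, electrodes)
        train_idx, test_idx = stratified_split(dataset.labels,
                                               cfg.test_fraction, cfg.seed)
        tcfg = TrainConfig(cfg.epochs, cfg.batch_size, cfg.teaching_rate,
                           cfg.seed)

        stage = "train"
        log.info("stage=%s", stage)
        tr_x = [tensors[i] for i in train_idx]
        tr_y = [dataset.labels[i] for i in train_idx]
        model = EmotionDecoder(tr_x, tr_y, electrodes=electrodes,
                               montage=montage, w_decay=cfg.w_decay)
        fit = model.fit(tcfg)
        rep = evaluate(fit.predict([tensors[i] for i in test_idx]),
                       [dataset.labels[i] for i in test_idx], task="binary")
        _write_csv(pd.DataFrame([{"task": f"{cfg.emotion}_vs_neutral",
                                  "accuracy": rep.accuracy, "f1": rep.f1,
                                  "chance": rep.chance_level,
                                  "train_accuracy": fit.train_accuracy,
                                  "final_loss": fit.loss_history[-1]}]),
                   out / "decoder_metrics.csv", cfg)
        (out / "decoder_summary.txt").write_text(_stamp(cfg) + "\n"
                                                 + fit.summary() + "\n")

        # --- mine ---------------------------------------------------------
        stage = "mine"
        log.info("stage=%s", stage)
        traces: dict[int, MiningTrace] = {}
        rows = []
        for sid in cfg.mine_subnetworks:
            trace = mine_subnetwork(tensors, list(dataset.labels),
                                    subnets[sid], train_idx, test_idx,
                                    montage, cfg=tcfg,
                                    contribution=cfg.contribution,
                                    w_decay=cfg.w_decay)
            traces[sid] = trace
            rows.extend(trace_to_rows(trace))
        _write_csv(pd.DataFrame(rows), out / "mining_traces.csv", cfg)

        # --- fuse ---------------------------------------------------------
        stage = "fuse"
        log.info("stage=%s", stage)
        points_best, points_simp = [], []
        for sid, trace in traces.items():
            b, s = select_best_simplest(trace)
            points_best.append((PerformancePoint(sid, "best",
                                                 b.performance.accuracy,
                                                 b.performance.f1), b))
            points_simp.append((PerformancePoint(sid, "simplest",
                                                 s.performance.accuracy,
                                                 s.performance.f1), s))
        if len(points_best) >= 2:
            km_b = kmeans_2([p for p, _ in points_best], seed=cfg.seed)
            members_b = high_cluster(points_best, km_b)
        else:
            members_b = points_best
        if len(points_simp) >= 2:
            km_s = kmeans_2([p for p, _ in points_simp], seed=cfg.seed)
            members_s = high_cluster(points_simp, km_s)
        else:
            members_s = points_simp
        bfm = build_fusion(tensors, list(dataset.labels),
                           [st.electrodes for _, st in members_b],
                           [p.subnetwork for p, _ in members_b],
                           train_idx, test_idx, montage, tcfg,
                           w_decay=cfg.w_decay)
        sfm = build_fusion(tensors, list(dataset.labels),
                           [st.electrodes for _, st in members_s],
                           [p.subnetwork for p, _ in members_s],
                           train_idx, test_idx, montage, tcfg,
                           w_decay=cfg.w_decay)
        best_point = max((p for p, _ in points_best), key=lambda p: p.accuracy)
        report = rank_models(bfm, sfm, best_point)
        _write_csv(report.reset_index(), out / "fusion_report.csv", cfg)

        # --- bands + MKL --------------------------------------------------
        stage = "bands"
        log.info("stage=%s", stage)
        band_res = band_decode_all(dataset, list(dataset.labels), electrodes,
                                   train_idx, test_idx, montage, tcfg,
                                   w_decay=cfg.w_decay)
        _write_csv(pd.DataFrame([{"band": b, "accuracy": a, "f1": f}
                                 for b, (a, f) in band_res.items()]),
                   out / "band_decoding.csv", cfg)

        stage = "mkl"
        log.info("stage=%s", stage)
        blocks = band_feature_blocks(dataset, list(dataset.labels), electrodes)
        contribs = easymkl_contributions(blocks, list(dataset.labels))
        _write_csv(pd.DataFrame([{"band": b, "contribution_percent": c}
                                 for b, c in contribs.items()]),
                   out / "mkl_contributions.csv", cfg)

        # --- granger ------------------------------------------------------
        stage = "granger"
        log.info("stage=%s", stage)
        idx = [dataset.montage.index(e) if hasattr(dataset, "montage") else None
               for e in cfg.gc_electrodes]
        trials = [rec.pick(cfg.gc_electrodes).data
                  for rec, lbl in zip(dataset.recordings, dataset.labels)
                  if lbl == cfg.emotion]
        net = directed_network(trials, cfg.fs, tuple(cfg.gc_electrodes),
                               BANDS[cfg.gc_band], cfg.gc_band,
                               order=cfg.gc_order,
                               n_surrogates=cfg.gc_surrogates, seed=cfg.seed)
        _write_csv(pd.DataFrame(net.edges or [],
                                columns=["source", "sink", "band", "strength"]),
                   out / "granger_edges.csv", cfg)

        cfg.to_yaml(out / "config.yaml")
        (out / "provenance.json").write_text(json.dumps(
            {"config_hash": cfg.hash(), "seed": cfg.seed,
             "version": sbpsnn.__version__,
             "elapsed_s": round(time.time() - t0, 1)}, indent=2))
        log.info("pipeline complete in %.1fs", time.time() - t0)
        return out
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
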