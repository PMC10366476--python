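"""Clustering of subnetwork model performances and fusion-model ranking.

The per-subnetwork best and simplest models are clustered (K-means,
k = 2, on standardised accuracy/F1) to find the high-performing group;
pooling the electrode sets of that group's models yields the best fusion
model (BFM, from best models) and the simplest fusion model (SFM, from
simplest models).  These are compared against the best single-subnetwork
model (BSM) on a common held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sbpsnn.evaluation import evaluate
from sbpsnn.snn import EmotionDecoder, TrainConfig


@dataclass(frozen=True)
class PerformancePoint:
    subnetwork: int
    kind: str                   # "best" | "simplest"
    accuracy: float             # percent
    f1: float


@dataclass
class KMeansResult:
    labels: np.ndarray
    centers: np.ndarray          # in standardised feature space
    objective: list              # within-cluster sum of squares per iteration
    degenerate: bool             # all points identical


def kmeans_2(points, seed: int = 0, n_restarts: int = 10) -> KMeansResult:
    """K-means with k=2 on (accuracy, f1) pairs.

    Features are standardised to zero mean / unit variance before
    clustering (the two scales differ by two orders of magnitude); Lloyd
    iterations run to convergence with the best of ``n_restarts``
    seeded initialisations kept (by within-cluster sum of squares).  The
    per-iteration objective of the winning restart is recorded and is
    non-increasing.
    """
    X = np.asarray([(p.accuracy, p.f1) if isinstance(p, PerformancePoint)
                    else tuple(p) for p in points], dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 points")
    sd = X.std(axis=0)
    degenerate = bool(np.all(sd < 1e-12))
    Z = (X - X.mean(axis=0)) / np.where(sd < 1e-12, 1.0, sd)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        idx = rng.choice(len(Z), size=2, replace=False)
        centers = Z[idx].copy()
        objective = []
        labels = np.zeros(len(Z), dtype=int)
        for _it in range(100):
            d = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = d.argmin(axis=1)
            objective.append(float(d[np.arange(len(Z)), labels].sum()))
            new_centers = centers.copy()
            for c in range(2):
                if np.any(labels == c):
                    new_centers[c] = Z[labels == c].mean(axis=0)
            if np.allclose(new_centers, centers):
                break
            centers = new_centers
        if best is None or objective[-1] < best.objective[-1]:
            best = KMeansResult(labels, centers, objective, degenerate)
    return best


def high_cluster(points, km: KMeansResult) -> list:
    """The members of the cluster with the higher mean accuracy."""
    acc = np.asarray([p.accuracy if isinstance(p, PerformancePoint) else p[0]
                      for p in points], dtype=float)
    means = [acc[km.labels == c].mean() if np.any(km.labels == c) else -np.inf
             for c in range(2)]
    keep = int(np.argmax(means))
    return [p for p, lbl in zip(points, km.labels) if lbl == keep]


def pool_electrodes(member_sets) -> tuple[str, ...]:
    """Order-preserving union of the member models' electrode sets."""
    seen: dict[str, None] = {}
    for s in member_sets:
        for e in s:
            seen.setdefault(e)
    pooled = tuple(seen)
    if not pooled:
        raise ValueError("pooled electrode set is empty")
    return pooled


@dataclass
class FusionModel:
    members: tuple                 # subnetwork ids
    electrodes: tuple[str, ...]
    fit: object
    accuracy: float
    f1: float


def build_fusion(spike_tensors, labels, member_sets, member_ids,
                 train_idx, test_idx, montage, cfg: TrainConfig | None = None,
                 **model_kwargs) -> FusionModel:
    """Train one decoder on the pooled electrodes of the member models."""
    electrodes = pool_electrodes(member_sets)
    cfg = cfg or TrainConfig()
    tr_x = [spike_tensors[i] for i in train_idx]
    tr_y = [labels[i] for i in train_idx]
    te_x = [spike_tensors[i] for i in test_idx]
    te_y = [labels[i] for i in test_idx]
    model = EmotionDecoder(tr_x, tr_y, electrodes=electrodes, montage=montage,
                           **model_kwargs)
    fit = model.fit(cfg)
    rep = evaluate(fit.predict(te_x), te_y,
                   task="binary" if len(model.classes) == 2 else "four_class")
    return FusionModel(tuple(member_ids), electrodes, fit,
                       rep.accuracy, rep.f1)


def rank_models(bfm: FusionModel, sfm: FusionModel, bsm) -> pd.DataFrame:
    """Side-by-side report of BFM / SFM / BSM performance.

    ``bsm`` may be a FusionModel or any object with ``accuracy`` and
    ``f1``.  No ordering is asserted — the table reports the data.
    """
    rows = []
    for name, m in (("BFM", bfm), ("SFM", sfm), ("BSM", bsm)):
        rows.append({"model": name, "accuracy": float(m.accuracy),
                     "f1": float(m.f1)})
    df = pd.DataFrame(rows).set_index("model")
    df["rank"] = df["accuracy"].rank(ascending=False, method="min").astype(int)
    return df
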