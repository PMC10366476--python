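"""Threshold spike encoding and the 471-node spatial grid.

Continuous signals are converted to binary ON/OFF spike trains with a
cumulative temporal-contrast (sigma-delta) code: a shared accumulator
integrates the signed sample-to-sample change and emits an ON spike when
it exceeds +theta (subtracting theta) or an OFF spike below -theta, with
theta = k times the standard deviation of the first difference per
channel.  Electrodes are mapped onto a 471-node lattice (1 cm spacing)
clipped to an ellipsoidal brain volume, by nearest-neighbour assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sbpsnn.montage import Montage
from sbpsnn.preprocess import EEGRecording

N_GRID_NODES = 471

# Ellipsoid semi-axes (x right, y anterior, z superior, mm) whose interior
# contains exactly 471 points of the 10 mm lattice.
_GRID_AXES_MM = np.array([0.75, 0.9, 0.7]) * 6.152 * 10.0
_BOUND_MARGIN = 1.6


@dataclass
class SpikeTensor:
    """Binary spike trains, input neurons x time steps."""

    spikes: np.ndarray
    dt: float
    neuron_map: tuple[tuple[str, str], ...]   # (electrode, polarity) per neuron

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be neurons x steps")
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValueError("spike entries must be binary")
        if len(self.neuron_map) != self.spikes.shape[0]:
            raise ValueError("one (electrode, polarity) entry per neuron required")
        self.spikes = self.spikes.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def to_coo(self):
        """Sparse (neuron, step) coordinate list plus a JSON-able header."""
        nz = np.argwhere(self.spikes == 1)
        header = {"dt": self.dt, "n_neurons": self.n_neurons,
                  "n_steps": self.n_steps, "neuron_map": list(map(list, self.neuron_map))}
        return nz, header

    @classmethod
    def from_coo(cls, coords, header) -> "SpikeTensor":
        spikes = np.zeros((header["n_neurons"], header["n_steps"]), dtype=np.uint8)
        coords = np.asarray(coords, dtype=int)
        if len(coords):
            spikes[coords[:, 0], coords[:, 1]] = 1
        return cls(spikes, header["dt"], tuple(tuple(m) for m in header["neuron_map"]))


def encode_threshold(rec: EEGRecording | np.ndarray, k: float = 0.5,
                     dt: float | None = None, labels=None,
                     theta: float | np.ndarray | None = None) -> SpikeTensor:
    """Cumulative temporal-contrast encoding, two neurons (ON/OFF) per channel.

    The per-channel threshold is ``k`` times the standard deviation of the
    first difference (or ``theta`` directly when given); constant channels
    encode to all-zero trains with a warning.
    """
    if k <= 0:
        raise ValueError("threshold factor k must be positive")
    if isinstance(rec, EEGRecording):
        data, labels, dt = rec.data, rec.labels, 1.0 / rec.fs
    else:
        data = np.atleast_2d(np.asarray(rec, dtype=float))
        if dt is None:
            raise ValueError("dt required for raw-array input")
        if labels is None:
            labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    if not np.all(np.isfinite(data)):
        raise ValueError("signal must be finite")

    n_ch, n_samp = data.shape
    if theta is not None:
        thetas = np.broadcast_to(np.asarray(theta, dtype=float), (n_ch,)).copy()
        if np.any(thetas <= 0):
            raise ValueError("explicit theta must be positive")
    else:
        diffs = np.diff(data, axis=1)
        thetas = k * diffs.std(axis=1)
    spikes = np.zeros((2 * n_ch, n_samp), dtype=np.uint8)
    for c in range(n_ch):
        theta = thetas[c]
        if theta == 0.0:
            warnings.warn(f"constant channel {labels[c]!r}: all-zero spike trains")
            continue
        acc = 0.0
        for t in range(1, n_samp):
            acc += data[c, t] - data[c, t - 1]
            # binary code: at most one spike per polarity per step; any
            # surplus carries over and is emitted on subsequent steps
            if acc >= theta:
                spikes[2 * c, t] = 1
                acc -= theta
            elif acc <= -theta:
                spikes[2 * c + 1, t] = 1
                acc += theta
    neuron_map = tuple((labels[c], pol) for c in range(n_ch) for pol in ("on", "off"))
    return SpikeTensor(spikes, dt, neuron_map)


@dataclass
class NodeGrid:
    """471 lattice nodes plus electrode -> nearest-node assignment."""

    nodes: np.ndarray
    electrode_assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.shape != (N_GRID_NODES, 3):
            raise ValueError(f"grid must have exactly {N_GRID_NODES} nodes")


def _lattice_nodes() -> np.ndarray:
    r = np.arange(-15, 16) * 10.0
    g = np.array(np.meshgrid(r, r, r, indexing="ij")).reshape(3, -1).T
    inside = ((g / _GRID_AXES_MM) ** 2).sum(axis=1) <= 1.0
    nodes = g[inside]
    # deterministic ordering: z, then y, then x
    order = np.lexsort((nodes[:, 0], nodes[:, 1], nodes[:, 2]))
    return nodes[order]


def build_node_grid(montage: Montage) -> NodeGrid:
    """Build the 471-node grid and assign each electrode its nearest node.

    Electrodes sit on the scalp while the nodes fill a brain-sized
    ellipsoid, so scalp sites project onto the outer node shell; ties are
    broken by the lowest node index.  Electrodes outside the grid's
    bounding volume (ellipsoid box with a 1.6x margin) are rejected.
    """
    nodes = _lattice_nodes()
    bound = _GRID_AXES_MM * _BOUND_MARGIN
    assignment: dict[str, int] = {}
    for lbl, pos in zip(montage.labels, montage.coords):
        if np.any(np.abs(pos) > bound):
            raise ValueError(f"electrode {lbl!r} outside the grid bounding volume")
        d2 = ((nodes - pos) ** 2).sum(axis=1)
        assignment[lbl] = int(np.argmin(d2))   # argmin takes the lowest index on ties
    return NodeGrid(nodes, assignment)


def allocate_input_streams(electrodes, n_inputs: int = 100) -> tuple[tuple[str, str], ...]:
    """Map ``n_inputs`` input neurons onto (electrode, polarity) streams.

    For subsets with at most ``n_inputs // 2`` electrodes every electrode
    receives an ON and an OFF neuron and the remaining neurons repeat the
    streams round-robin; for larger subsets the ON streams of all
    electrodes are allocated first, then OFF streams until the pool is
    full, so no electrode is dropped.
    """
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("empty electrode set")
    if 2 * len(electrodes) <= n_inputs:
        streams = [(e, pol) for e in electrodes for pol in ("on", "off")]
    else:
        streams = [(e, "on") for e in electrodes] + [(e, "off") for e in electrodes]
    return tuple(streams[i % len(streams)] for i in range(n_inputs))


def project_spikes(tensor: SpikeTensor, stream_map) -> np.ndarray:
    """Gather the spike rows of ``stream_map`` from an ON/OFF spike tensor."""
    index = {m: i for i, m in enumerate(tensor.neuron_map)}
    rows = []
    for stream in stream_map:
        if stream not in index:
            raise KeyError(f"stream {stream} absent from spike tensor")
        rows.append(tensor.spikes[index[stream]])
    return np.array(rows, dtype=np.uint8)
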