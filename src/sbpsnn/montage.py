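"""Idealised 62-channel 10-20 electrode montage with 3-D coordinates.

Coordinates live in a Talairach-like right-handed frame (x to the right
ear, y anterior, z superior, millimetres) on a sphere of radius
``SCALP_RADIUS_MM``.  Positions are constructed geometrically from the
10-20 arc scheme, so left/right homologue pairs are mirror images in x by
construction and the vertex electrode Cz sits exactly at (0, 0, R).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SCALP_RADIUS_MM = 63.0

# Midline inclination of each electrode row, degrees anterior (+) of vertex.
_ROW_INCLINATION = {
    "Fp": 72.0, "AF": 54.0, "F": 36.0, "FC": 18.0, "C": 0.0,
    "CP": -18.0, "P": -36.0, "PO": -54.0, "O": -72.0,
}
# FT/TP electrodes sit on the FC/CP rows, far laterally.
_ROW_ALIAS = {"FT": "FC", "TP": "CP", "T": "C"}

_LABELS_62 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def _parse_label(label: str) -> tuple[str, str]:
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unrecognised 10-20 electrode label: {label!r}")
    return m.group(1), m.group(2)


def _lateral_angle(row: str, suffix: str) -> float:
    """Signed lateral arc angle (degrees, right positive) for a label suffix."""
    if suffix == "z":
        return 0.0
    n = int(suffix)
    sign = 1.0 if n % 2 == 0 else -1.0
    if row in ("T",):
        return sign * 90.0
    if row in ("FT", "TP"):
        return sign * 81.0
    return sign * 18.0 * ((n + 1) // 2)


def _position(label: str, radius: float) -> np.ndarray:
    row, suffix = _parse_label(label)
    base_row = _ROW_ALIAS.get(row, row)
    if base_row not in _ROW_INCLINATION:
        raise ValueError(f"unknown electrode row {row!r} in label {label!r}")
    beta = np.deg2rad(_ROW_INCLINATION[base_row])
    gamma = np.deg2rad(_lateral_angle(row, suffix))
    # Midline point of the row, then rotate along the great circle through
    # the ears: p = cos(gamma) * M + sin(gamma) * R * x_hat.
    mid = radius * np.array([0.0, np.sin(beta), np.cos(beta)])
    return np.cos(gamma) * mid + np.sin(gamma) * radius * np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class Montage:
    """Electrode labels with 3-D positions (mm)."""

    labels: tuple[str, ...]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite electrode coordinates")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def coord(self, label: str) -> np.ndarray:
        return self.coords[self.index(label)]

    def subset(self, labels) -> "Montage":
        idx = [self.index(lbl) for lbl in labels]
        return Montage(tuple(labels), self.coords[idx])

    def homolog_pairs(self) -> list[tuple[str, str]]:
        """(left, right) label pairs: odd suffix paired with suffix + 1."""
        pairs = []
        for lbl in self.labels:
            row, suffix = _parse_label(lbl)
            if suffix != "z" and int(suffix) % 2 == 1:
                partner = f"{row}{int(suffix) + 1}"
                if partner in self.labels:
                    pairs.append((lbl, partner))
        return pairs

    def to_tsv(self, path) -> None:
        lines = ["label\tx\ty\tz"]
        for lbl, (x, y, z) in zip(self.labels, self.coords):
            lines.append(f"{lbl}\t{x:.6f}\t{y:.6f}\t{z:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "Montage":
        rows = [ln.split("\t") for ln in Path(path).read_text().strip().splitlines()[1:]]
        labels = tuple(r[0] for r in rows)
        coords = np.array([[float(v) for v in r[1:4]] for r in rows])
        return cls(labels, coords)


def standard_montage_62(radius_mm: float = SCALP_RADIUS_MM) -> Montage:
    """The 62-channel 10-20 montage used throughout the package.

    Covers the Fp/AF/F/FC/FT/C/T/CP/TP/P/PO/O rows so that each of the
    seven scalp subnetworks (prefrontal, frontal, frontal-central,
    central-temporal, centro-parietal, parietal, parieto-occipital) is
    non-empty.
    """
    coords = np.array([_position(lbl, radius_mm) for lbl in _LABELS_62])
    return Montage(_LABELS_62, coords)
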