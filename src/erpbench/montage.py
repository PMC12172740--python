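"""Electrode montage: channel identities and idealized unit-sphere geometry.

The montage carries everything downstream stages need to know about sensor
space: channel labels, 3-D positions on an idealized unit sphere (head center
at the origin, vertex at +z, nose at +y), and an angular neighborhood radius
that defines spatial adjacency for neighbor-weighted interpolation and for
channel x time clustering.

The shipped 32-channel layout is an extended 10-20 set including the
fronto-central midline electrode FCz (the canonical reward-positivity
channel) and the mastoid electrodes TP9/TP10 used for linked-mastoid
re-referencing. Positions are idealized spherical coordinates, not digitized
head shapes; they are adequate for spherical-spline and inverse-distance
interpolation and for adjacency, which is all this package uses them for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Montage",
    "standard_montage_32",
    "load_montage_tsv",
    "save_montage_tsv",
    "STANDARD_32_LABELS",
]

# (azimuth deg from +x toward +y, polar deg from vertex) per label.
# Outer 10-20 ring at polar 90, mastoids below the equator.
_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (108.0, 90.0), "Fp2": (72.0, 90.0),
    "F7": (144.0, 90.0), "F3": (129.0, 63.0), "Fz": (90.0, 45.0),
    "F4": (51.0, 63.0), "F8": (36.0, 90.0),
    "FC5": (151.0, 69.0), "FC1": (116.0, 31.0), "FCz": (90.0, 22.5),
    "FC2": (64.0, 31.0), "FC6": (29.0, 69.0),
    "T7": (180.0, 90.0), "C3": (180.0, 45.0), "Cz": (0.0, 0.0),
    "C4": (0.0, 45.0), "T8": (0.0, 90.0),
    "TP9": (198.0, 108.0), "CP5": (209.0, 69.0), "CP1": (244.0, 31.0),
    "CP2": (296.0, 31.0), "CP6": (331.0, 69.0), "TP10": (342.0, 108.0),
    "P7": (216.0, 90.0), "P3": (231.0, 63.0), "Pz": (270.0, 45.0),
    "P4": (309.0, 63.0), "P8": (324.0, 90.0),
    "POz": (270.0, 67.5), "O1": (252.0, 90.0), "Oz": (270.0, 90.0),
    "O2": (288.0, 90.0),
}

STANDARD_32_LABELS: tuple[str, ...] = tuple(_ANGLES)


def _sph_to_cart(azimuth_deg: float, polar_deg: float) -> tuple[float, float, float]:
    az = math.radians(azimuth_deg)
    th = math.radians(polar_deg)
    return (math.sin(th) * math.cos(az), math.sin(th) * math.sin(az), math.cos(th))


@dataclass(frozen=True)
class Montage:
    """Channel labels plus unit-sphere positions and an adjacency radius.

    Parameters
    ----------
    channel_names
        Unique channel labels, in recording order.
    positions
        ``(n_channels, 3)`` array of unit-norm positions.
    neighbor_radius
        Angular distance (radians) under which two distinct channels are
        considered spatial neighbors. Default 0.6 rad captures nearest
        neighbors on the idealized 10-20 grid.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray
    neighbor_radius: float = 0.6
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        if len(set(names)) != len(names):
            raise ValueError("montage channel names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(names), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(names)} channels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must have unit norm")
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def angular_distances(self) -> np.ndarray:
        """Pairwise great-circle distances (radians), zero on the diagonal."""
        cosines = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cosines)

    def adjacency(self, radius: float | None = None) -> np.ndarray:
        """Boolean symmetric, irreflexive neighbor matrix."""
        r = self.neighbor_radius if radius is None else radius
        dist = self.angular_distances()
        adj = dist < r
        np.fill_diagonal(adj, False)
        return adj

    def subset(self, names: list[str] | tuple[str, ...]) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(tuple(names), self.positions[idx], self.neighbor_radius)


def standard_montage_32(neighbor_radius: float = 0.6) -> Montage:
    """The package's standard 32-channel extended 10-20 montage."""
    with resources.as_file(
        resources.files("erpbench.data").joinpath("montage32.tsv")
    ) as path:
        mont = load_montage_tsv(path)
    if neighbor_radius != mont.neighbor_radius:
        mont = Montage(mont.channel_names, mont.positions, neighbor_radius)
    return mont


def load_montage_tsv(path: str | Path) -> Montage:
    """Read a montage from TSV columns ``label  x  y  z``."""
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("label"):
                continue
            parts = line.split("\t")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return Montage(tuple(names), np.asarray(rows))


def save_montage_tsv(montage: Montage, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for name, (x, y, z) in zip(montage.channel_names, montage.positions):
            fh.write(f"{name}\t{x:.12f}\t{y:.12f}\t{z:.12f}\n")


def _build_standard_positions() -> np.ndarray:
    return np.array([_sph_to_cart(*_ANGLES[n]) for n in STANDARD_32_LABELS])
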