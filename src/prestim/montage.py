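"""Electrode montage: 2-D sensor layout and channel neighbourhood graph.

Cluster-based permutation statistics over channel x frequency x time need a
channel adjacency structure.  Neighbourhoods are defined by Euclidean
distance between 2-D projected sensor positions, with the distance cutoff
auto-calibrated so that the median number of neighbours per channel is close
to a target (default 6, a typical value for 60-ish channel caps).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["Montage", "build_adjacency", "load_acticap60"]


@dataclass(frozen=True)
class Montage:
    """Channel labels, 2-D projected positions and the neighbour graph.

    Attributes
    ----------
    channels : tuple of str
        10-20 system channel labels, unique.
    positions : ndarray, shape (n_channels, 2)
        Azimuthal-equidistant projection of scalp positions (vertex at the
        origin, arbitrary units).
    adjacency : ndarray of bool, shape (n_channels, n_channels)
        Symmetric, irreflexive neighbour matrix.
    """

    channels: tuple
    positions: np.ndarray
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        n = len(self.channels)
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n_channels, 2)")
        a = self.adjacency
        if a.shape != (n, n) or a.dtype != bool:
            raise ValueError("adjacency must be a boolean (n, n) matrix")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must be irreflexive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def neighbours(self, label: str) -> tuple:
        row = self.adjacency[self.index(label)]
        return tuple(c for c, keep in zip(self.channels, row) if keep)

    def subset(self, labels, target_median_degree: float = 6.0) -> "Montage":
        """Montage restricted to ``labels`` with a re-calibrated graph."""
        idx = [self.index(lb) for lb in labels]
        pos = self.positions[idx]
        return Montage(tuple(labels), pos, build_adjacency(pos, target_median_degree))


def build_adjacency(positions: np.ndarray, target_median_degree: float = 6.0) -> np.ndarray:
    """Distance-threshold neighbour matrix over 2-D positions.

    The threshold is the smallest pairwise distance at which the median
    degree reaches ``target_median_degree``; any channel left isolated is
    connected to its nearest neighbour so that every channel has at least
    one neighbour.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        raise ValueError("need at least two channels")
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    cand = np.unique(d[np.triu_indices(n, k=1)])
    adj = None
    for th in cand:
        adj = (d <= th) & ~np.eye(n, dtype=bool)
        if np.median(adj.sum(axis=1)) >= target_median_degree:
            break
    # connect isolated channels to their nearest neighbour
    for i in np.flatnonzero(adj.sum(axis=1) == 0):
        j = np.argmin(np.where(np.arange(n) == i, np.inf, d[i]))
        adj[i, j] = adj[j, i] = True
    return adj


def load_acticap60(target_median_degree: float = 6.0) -> Montage:
    """The default 60-channel 10-20 scalp montage shipped with the package."""
    with resources.files("prestim.data").joinpath("acticap60_layout.csv").open() as f:
        rows = list(csv.DictReader(f))
    channels = tuple(r["label"] for r in rows)
    positions = np.array([[float(r["x"]), float(r["y"])] for r in rows])
    return Montage(channels, positions, build_adjacency(positions, target_median_degree))
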