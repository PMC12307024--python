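"""Scalp montage and spatial adjacency.

A :class:`Montage` is the spatial backbone of the whole analysis: it fixes
the channel order used by every data array and the neighborhood graph used
by channel interpolation, cluster formation in the permutation test, and
the electrode-selection procedure.

The default montage has 31 scalp channels labelled in the 10-20 scheme,
laid out on a schematic 2-D grid; two channels are neighbors when their
grid distance is below a fixed radius. The resulting graph is symmetric,
irreflexive and connected (asserted at construction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Montage", "default_montage", "DEFAULT_CHANNEL_POSITIONS"]

# Schematic head coordinates (x: left-negative, y: front-positive).
# Units are arbitrary grid steps; only relative distances matter.
DEFAULT_CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.7, 3.5), "Fp2": (0.7, 3.5),
    "F7": (-2.0, 2.5), "F3": (-1.0, 2.5), "Fz": (0.0, 2.5),
    "F4": (1.0, 2.5), "F8": (2.0, 2.5),
    "FC5": (-1.5, 1.5), "FC1": (-0.5, 1.5), "FC2": (0.5, 1.5), "FC6": (1.5, 1.5),
    "T7": (-2.0, 0.5), "C3": (-1.0, 0.5), "Cz": (0.0, 0.5),
    "C4": (1.0, 0.5), "T8": (2.0, 0.5),
    "CP5": (-1.5, -0.5), "CP1": (-0.5, -0.5), "CP2": (0.5, -0.5), "CP6": (1.5, -0.5),
    "P7": (-2.0, -1.5), "P3": (-1.0, -1.5), "Pz": (0.0, -1.5),
    "P4": (1.0, -1.5), "P8": (2.0, -1.5),
    "PO3": (-0.8, -2.5), "POz": (0.0, -2.5), "PO4": (0.8, -2.5),
    "O1": (-0.7, -3.3), "Oz": (0.0, -3.3), "O2": (0.7, -3.3),
}

_NEIGHBOR_RADIUS = 1.45


@dataclass(frozen=True)
class Montage:
    """Named channels plus a symmetric adjacency graph.

    Parameters
    ----------
    channel_names
        Ordered channel labels; this order is the canonical channel axis
        everywhere in the package.
    adjacency
        Unordered neighbor pairs ``frozenset({a, b})``.
    """

    channel_names: tuple[str, ...]
    adjacency: frozenset[frozenset[str]]
    positions: dict[str, tuple[float, float]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        for pair in self.adjacency:
            if len(pair) != 2:
                raise ValueError(f"adjacency pair {set(pair)} is not a 2-set")
            unknown = set(pair) - set(names)
            if unknown:
                raise ValueError(f"adjacency refers to unknown channels {unknown}")
        if not self._connected():
            raise ValueError("montage adjacency graph is not connected")

    def _connected(self) -> bool:
        if not self.channel_names:
            return False
        seen = {self.channel_names[0]}
        stack = [self.channel_names[0]]
        while stack:
            ch = stack.pop()
            for nb in self.neighbors(ch):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.channel_names)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def neighbors(self, name: str) -> tuple[str, ...]:
        """Neighbors of ``name``, in montage order."""
        self.index(name)
        nbs = {next(iter(p - {name})) for p in self.adjacency if name in p}
        return tuple(ch for ch in self.channel_names if ch in nbs)

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean (n_channels, n_channels) neighbor matrix."""
        n = self.n_channels
        idx = {c: i for i, c in enumerate(self.channel_names)}
        mat = np.zeros((n, n), dtype=bool)
        for pair in self.adjacency:
            a, b = tuple(pair)
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = True
        return mat

    # -- serialization --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": list(self.channel_names),
            "adjacency": sorted(sorted(p) for p in self.adjacency),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        for key in ("channels", "adjacency"):
            if key not in payload:
                raise ValueError(f"montage JSON missing field {key!r}")
        return cls(
            channel_names=tuple(payload["channels"]),
            adjacency=frozenset(frozenset(p) for p in payload["adjacency"]),
        )


def default_montage() -> Montage:
    """The 31-channel 10-20 scalp montage used throughout the package."""
    names = tuple(DEFAULT_CHANNEL_POSITIONS)
    pos = DEFAULT_CHANNEL_POSITIONS
    pairs = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = np.hypot(pos[a][0] - pos[b][0], pos[a][1] - pos[b][1])
            if d <= _NEIGHBOR_RADIUS:
                pairs.add(frozenset({a, b}))
    return Montage(channel_names=names, adjacency=frozenset(pairs),
                   positions=dict(pos))
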