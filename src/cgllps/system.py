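"""Core containers: configurations and trajectories.

A :class:`Configuration` stores bead positions in an orthorhombic periodic
box together with per-bead chain ids and residue codes.  Chains are
contiguous runs of beads; harmonic bonds connect sequence neighbours within
a chain only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Configuration:
    positions: np.ndarray  # (N, 3) nm, wrapped into the box
    box: np.ndarray  # (3,) nm
    chain_ids: np.ndarray  # (N,) int
    residues: np.ndarray  # (N,) unicode one-letter codes
    velocities: np.ndarray | None = None  # (N, 3) nm/ps

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.chain_ids = np.asarray(self.chain_ids, dtype=np.int64)
        self.residues = np.asarray(self.residues, dtype="U1")
        n = len(self.positions)
        if not (len(self.chain_ids) == len(self.residues) == n):
            raise ValueError("positions, chain_ids and residues must have equal length")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def wrap(self) -> None:
        """Wrap positions into [0, L) along each axis."""
        self.positions -= self.box * np.floor(self.positions / self.box)

    def bonds(self) -> np.ndarray:
        """(B, 2) array of bonded bead indices (sequence neighbours)."""
        same_chain = self.chain_ids[:-1] == self.chain_ids[1:]
        idx = np.nonzero(same_chain)[0]
        return np.column_stack([idx, idx + 1]).astype(np.int64)

    def masses(self, residue_masses: dict[str, float]) -> np.ndarray:
        return np.array([residue_masses[str(c)] for c in self.residues])

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            self.box.copy(),
            self.chain_ids.copy(),
            self.residues.copy(),
            None if self.velocities is None else self.velocities.copy(),
        )


@dataclass
class Trajectory:
    """Time-ordered configuration frames with constant topology."""

    frames: list[Configuration] = field(default_factory=list)
    times: list[float] = field(default_factory=list)  # ps

    def append(self, frame: Configuration, time: float) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        if self.frames and frame.n_beads != self.frames[0].n_beads:
            raise ValueError("bead count must stay constant along a trajectory")
        self.frames.append(frame)
        self.times.append(time)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)
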