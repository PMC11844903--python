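"""Text interchange formats: LAMMPS data/dump files and a native trajectory.

The data-file writer emits a ``full``-style LAMMPS data file (atoms with
molecule id, type, charge) plus harmonic bonds, which is enough to run the
HPS-family models in an external engine.  The dump reader/writer handles
the plain-text ``id type x y z`` custom dump layout.  The native format is
a small self-describing CSV-per-frame container used for fixtures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .forcefield import ModelDefinition
from .system import Configuration, Trajectory


class IOError_(ValueError):
    pass


def write_lammps_data(
    path, configuration: Configuration, model: ModelDefinition, title: str = "cgllps system"
) -> None:
    """Write a LAMMPS ``full``-style data file with harmonic bonds."""
    cfg = configuration
    tab_codes = sorted(model.residues)
    type_of = {c: i + 1 for i, c in enumerate(tab_codes)}
    bonds = cfg.bonds()
    lines = [f"# {title}", ""]
    lines.append(f"{cfg.n_beads} atoms")
    lines.append(f"{len(bonds)} bonds")
    lines.append(f"{len(tab_codes)} atom types")
    lines.append("1 bond types")
    lines.append("")
    lines.append(f"0.0 {cfg.box[0]:.6f} xlo xhi")
    lines.append(f"0.0 {cfg.box[1]:.6f} ylo yhi")
    lines.append(f"0.0 {cfg.box[2]:.6f} zlo zhi")
    lines.append("")
    lines.append("Masses")
    lines.append("")
    for c in tab_codes:
        lines.append(f"{type_of[c]} {model.residues[c].mass:.4f}  # {c}")
    lines.append("")
    lines.append("Atoms  # full")
    lines.append("")
    for i in range(cfg.n_beads):
        c = str(cfg.residues[i])
        q = model.residues[c].charge
        x, y, z = cfg.positions[i]
        lines.append(
            f"{i + 1} {cfg.chain_ids[i] + 1} {type_of[c]} {q:.3f} "
            f"{x:.6f} {y:.6f} {z:.6f}"
        )
    if len(bonds):
        lines.append("")
        lines.append("Bonds")
        lines.append("")
        for b, (i, j) in enumerate(bonds):
            lines.append(f"{b + 1} 1 {i + 1} {j + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dump(path, trajectory: Trajectory, timesteps=None) -> None:
    """Write a plain-text custom dump (``id type x y z``) with type = chain id."""
    if timesteps is None:
        timesteps = list(range(len(trajectory)))
    chunks = []
    for step, frame in zip(timesteps, trajectory):
        chunks.append("ITEM: TIMESTEP")
        chunks.append(str(int(step)))
        chunks.append("ITEM: NUMBER OF ATOMS")
        chunks.append(str(frame.n_beads))
        chunks.append("ITEM: BOX BOUNDS pp pp pp")
        for L in frame.box:
            chunks.append(f"0.0 {L:.6f}")
        chunks.append("ITEM: ATOMS id mol element x y z")
        for i in range(frame.n_beads):
            x, y, z = frame.positions[i]
            chunks.append(
                f"{i + 1} {frame.chain_ids[i] + 1} {frame.residues[i]} "
                f"{x:.6f} {y:.6f} {z:.6f}"
            )
    Path(path).write_text("\n".join(chunks) + "\n")


def read_dump(path) -> Trajectory:
    """Read a plain-text custom dump written by :func:`write_dump`."""
    lines = Path(path).read_text().splitlines()
    traj = Trajectory()
    k = 0
    while k < len(lines):
        if not lines[k].startswith("ITEM: TIMESTEP"):
            raise IOError_(f"line {k + 1}: expected ITEM: TIMESTEP, got {lines[k]!r}")
        step = int(lines[k + 1])
        if not lines[k + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise IOError_(f"line {k + 3}: expected ITEM: NUMBER OF ATOMS")
        n = int(lines[k + 3])
        box = []
        for off in range(3):
            lo, hi = map(float, lines[k + 5 + off].split()[:2])
            box.append(hi - lo)
        header = lines[k + 8].split()[2:]
        required = ["id", "mol", "element", "x", "y", "z"]
        if header != required:
            raise IOError_(f"unsupported dump columns {header}; expected {required}")
        rows = [lines[k + 9 + i].split() for i in range(n)]
        rows.sort(key=lambda r: int(r[0]))
        pos = np.array([[float(r[3]), float(r[4]), float(r[5])] for r in rows])
        chain = np.array([int(r[1]) - 1 for r in rows])
        res = np.array([r[2] for r in rows], dtype="U1")
        traj.append(Configuration(pos, np.array(box), chain, res), float(step))
        k += 9 + n
    return traj


def write_trajectory_csv(path, trajectory: Trajectory) -> None:
    """Native columnar format: one long CSV with frame/time columns."""
    rows = []
    for t, frame in zip(trajectory.times, trajectory):
        for i in range(frame.n_beads):
            rows.append(
                (
                    t,
                    i,
                    int(frame.chain_ids[i]),
                    str(frame.residues[i]),
                    frame.positions[i, 0],
                    frame.positions[i, 1],
                    frame.positions[i, 2],
                )
            )
    df = pd.DataFrame(rows, columns=["t_ps", "bead", "chain", "residue", "x", "y", "z"])
    header = "# box_nm: " + " ".join(f"{v:.8f}" for v in trajectory.frames[0].box) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.8f")


def read_trajectory_csv(path) -> Trajectory:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# box_nm:"):
            raise IOError_("missing box header line")
        box = np.array([float(v) for v in first.split(":")[1].split()])
        df = pd.read_csv(fh)
    traj = Trajectory()
    for t, group in df.groupby("t_ps", sort=True):
        group = group.sort_values("bead")
        cfg = Configuration(
            group[["x", "y", "z"]].to_numpy(),
            box,
            group["chain"].to_numpy(),
            group["residue"].to_numpy(dtype="U1"),
        )
        traj.append(cfg, float(t))
    return traj


def write_stress_csv(path, stress) -> None:
    df = stress.to_frame()
    header = f"# volume_nm3: {stress.volume:.8f} temperature_K: {stress.temperature:.4f}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_stress_csv(path):
    from .rheology import StressSeries

    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# volume_nm3:"):
            raise IOError_("missing volume/temperature header line")
        parts = first.split()
        volume = float(parts[2])
        temperature = float(parts[4])
        df = pd.read_csv(fh)
    return StressSeries(
        df["t_ps"].to_numpy(),
        df["sxy"].to_numpy(),
        df["sxz"].to_numpy(),
        df["syz"].to_numpy(),
        df["sxx"].to_numpy(),
        df["syy"].to_numpy(),
        df["szz"].to_numpy(),
        volume,
        temperature,
    )
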