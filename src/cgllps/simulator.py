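"""System construction and Langevin dynamics at fixed volume.

Direct-coexistence systems are built by inserting chains as random walks in
an elongated periodic box (long axis z); bulk systems are built in a cube
and compressed isotropically in stages until the target density is reached.
Dynamics use BAOAB Langevin splitting at the model's published defaults
(time step 10 fs, thermostat relaxation 5 ps); with the thermostat disabled
the integrator reduces to velocity Verlet.  Per-stride output includes
potential/kinetic energy, instantaneous temperature, and the full virial
stress tensor, which feeds the Green-Kubo viscosity pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .constants import KB, MASS_DENSITY_TO_G_CM3, PRESSURE_KJ_NM3_TO_BAR
from .forcefield import ForceFieldError, ModelDefinition, total_energy_forces
from .neighbors import pair_list
from .rheology import StressSeries
from .sequences import ProteinSequence
from .system import Configuration, Trajectory


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationSettings:
    temperature: float  # K
    n_steps: int
    timestep: float = 10.0  # fs
    damping: float | None = 5.0  # ps; None disables the thermostat (velocity Verlet)
    seed: int = 0
    skin: float = 0.3  # nm, neighbour-list skin
    traj_stride: int = 0  # steps between stored frames (0 = only final frame)
    stress_stride: int = 100
    energy_stride: int = 100

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.damping is not None and self.damping <= 0:
            raise ValueError("thermostat damping must be positive")


# ---------------------------------------------------------------------------
# configuration builders
# ---------------------------------------------------------------------------


def mass_density(configuration: Configuration, model: ModelDefinition) -> float:
    """Mean mass density of the box in g/cm^3."""
    masses = configuration.masses(model.residue_masses)
    volume = float(np.prod(configuration.box))
    return float(masses.sum() / volume * MASS_DENSITY_TO_G_CM3)


def _insert_chains(
    model: ModelDefinition,
    sequence: ProteinSequence,
    n_chains: int,
    box: np.ndarray,
    rng: np.random.Generator,
    z_range: tuple[float, float],
    overlap_factor: float = 0.7,
    max_retries: int = 1000,
) -> Configuration:
    """Random-walk insertion of chains rejecting overlaps below 0.7 sigma_ij."""
    from scipy.spatial import cKDTree

    sigma = {c: p.sigma for c, p in model.residues.items()}
    try:
        seq_sigma = np.array([sigma[c] for c in sequence.residues])
    except KeyError as exc:
        raise ForceFieldError(f"unknown residue code {exc.args[0]!r}") from None
    r0 = model.bond_r0_nm
    L = len(sequence.residues)
    sig_max = seq_sigma.max()
    placed: list[np.ndarray] = []
    placed_sigma: list[float] = []

    def ok(pos, own_sigma, bonded_prev):
        if not placed:
            return True
        tree = cKDTree(
            (np.array(placed) % box), boxsize=box
        )  # rebuilt per bead: desk-scale systems only
        idx = tree.query_ball_point(pos % box, overlap_factor * sig_max)
        for i in idx:
            if i == bonded_prev:
                continue
            d = np.array(placed[i]) - pos
            d -= box * np.round(d / box)
            if np.linalg.norm(d) < overlap_factor * 0.5 * (placed_sigma[i] + own_sigma):
                return False
        return True

    chains = []
    for _ in range(n_chains):
        for attempt in range(max_retries):
            start_idx = len(placed)
            chain = []
            p = np.array(
                [
                    rng.uniform(0, box[0]),
                    rng.uniform(0, box[1]),
                    rng.uniform(z_range[0], z_range[1]),
                ]
            )
            if not ok(p, seq_sigma[0], -1):
                continue
            placed.append(p)
            placed_sigma.append(seq_sigma[0])
            chain.append(p)
            failed = False
            for b in range(1, L):
                success = False
                for _ in range(100):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    q = chain[-1] + r0 * v
                    if ok(q, seq_sigma[b], len(placed) - 1):
                        success = True
                        break
                if not success:
                    failed = True
                    break
                placed.append(q)
                placed_sigma.append(seq_sigma[b])
                chain.append(q)
            if not failed:
                chains.append(np.array(chain))
                break
            del placed[start_idx:]
            del placed_sigma[start_idx:]
        else:
            raise SimulationError(
                f"chain insertion failed after {max_retries} retries "
                f"({len(chains)} of {n_chains} placed)"
            )
    positions = np.vstack(chains)
    chain_ids = np.repeat(np.arange(n_chains), L)
    residues = np.array(list(sequence.residues) * n_chains)
    cfg = Configuration(positions, box, chain_ids, residues)
    cfg.wrap()
    return cfg


def build_slab_configuration(
    model: ModelDefinition,
    sequence: ProteinSequence,
    n_chains: int,
    cross_section: float = 17.0 * 17.0,  # nm^2
    length: float = 120.0,  # nm
    seed: int = 0,
    occupied_fraction: float = 1.0,
) -> Configuration:
    """Chains inserted into an elongated box (long axis z).

    ``occupied_fraction`` restricts insertion to a central z-window, which
    produces a pre-formed dense slab and shortens equilibration in
    desk-scale runs; the default fills the whole box.
    """
    side = float(np.sqrt(cross_section))
    box = np.array([side, side, float(length)])
    rng = np.random.default_rng(seed)
    half = 0.5 * length * occupied_fraction
    z_range = (0.5 * length - half, 0.5 * length + half)
    return _insert_chains(model, sequence, n_chains, box, rng, z_range)


def build_bulk_configuration(
    model: ModelDefinition,
    sequence: ProteinSequence,
    n_chains: int,
    target_density: float,  # g/cm^3
    seed: int = 0,
    relax_temperature: float = 300.0,
    stage_scale: float = 0.93,
    relax_steps: int = 200,
    density_tolerance: float = 0.01,
    max_stages: int = 200,
) -> Configuration:
    """Cubic box compressed isotropically in stages to the target density.

    Each stage rescales the box and positions, then relaxes briefly with
    Langevin dynamics; compression stops once the density is within 1% of
    the target.  Afterwards no bond may exceed twice its rest length.
    """
    if target_density <= 0:
        raise SimulationError("target density must be positive")
    masses = np.array([model.residue_masses[c] for c in sequence.residues])
    total_mass = masses.sum() * n_chains
    target_volume = total_mass / target_density * MASS_DENSITY_TO_G_CM3
    start_volume = target_volume * 8.0  # begin dilute: half the edge length target
    side = start_volume ** (1.0 / 3.0)
    box = np.array([side, side, side])
    rng = np.random.default_rng(seed)
    cfg = _insert_chains(model, sequence, n_chains, box, rng, (0.0, side))
    settings = SimulationSettings(
        temperature=relax_temperature,
        n_steps=relax_steps,
        seed=seed + 1,
        traj_stride=0,
        stress_stride=0,
        energy_stride=0,
    )
    for _ in range(max_stages):
        density = mass_density(cfg, model)
        if density >= target_density * (1.0 - density_tolerance):
            break
        needed = (density / target_density) ** (1.0 / 3.0)
        factor = max(stage_scale, needed)  # never overshoot the target
        cfg.positions *= factor
        cfg.box *= factor
        cfg.wrap()
        traj, _, _ = run_langevin(cfg, model, settings)
        cfg = traj.frames[-1]
    else:
        raise SimulationError(
            f"bulk compression did not converge; last density {mass_density(cfg, model):.4f} g/cm^3"
        )
    # sanity: compression must not have stretched bonds
    bonds = cfg.bonds()
    d = cfg.positions[bonds[:, 0]] - cfg.positions[bonds[:, 1]]
    d -= cfg.box * np.round(d / cfg.box)
    if np.linalg.norm(d, axis=1).max() > 2.0 * model.bond_r0_nm:
        raise SimulationError("bond stretched beyond twice its rest length during compression")
    return cfg


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    scale = np.sqrt(KB * temperature / masses)[:, None]
    return rng.normal(size=(len(masses), 3)) * scale


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2))
    dof = 3 * len(masses)
    return 2.0 * ke / (dof * KB)


def virial_stress(
    configuration: Configuration,
    velocities: np.ndarray,
    model: ModelDefinition,
    T: float = 298.0,
) -> np.ndarray:
    """Instantaneous stress tensor (kinetic + pairwise virial) in bar."""
    _, _, virial = total_energy_forces(model, configuration, T=T, return_virial=True)
    masses = configuration.masses(model.residue_masses)
    kin = (masses[:, None, None] * velocities[:, :, None] * velocities[:, None, :]).sum(axis=0)
    volume = float(np.prod(configuration.box))
    return (kin + virial) / volume * PRESSURE_KJ_NM3_TO_BAR


def run_langevin(
    configuration: Configuration,
    model: ModelDefinition,
    settings: SimulationSettings,
):
    """NVT Langevin dynamics (BAOAB splitting).

    Returns ``(Trajectory, StressSeries | None, energies DataFrame)``.  The
    stress series holds the six pressure-tensor components in bar at the
    requested stride; with ``stress_stride=0`` no stress is recorded.
    """
    cfg = configuration.copy()
    cfg.wrap()
    tab = model.tables(settings.temperature)
    tid = tab.type_ids(cfg.residues)
    bonds = cfg.bonds()
    masses = tab.masses[tid]
    rng = np.random.default_rng(settings.seed)
    dt = settings.timestep * 1e-3  # fs -> ps
    volume = float(np.prod(cfg.box))

    if cfg.velocities is None:
        vel = maxwell_boltzmann_velocities(masses, settings.temperature, rng)
    else:
        vel = cfg.velocities.copy()

    if settings.damping is not None:
        c1 = np.exp(-dt / settings.damping)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * settings.temperature / masses)[:, None]

    r_build = tab.max_cutoff + settings.skin
    pos = cfg.positions

    def build_pairs():
        return pair_list(pos, cfg.box, r_build, exclude=bonds)

    pairs = build_pairs()
    ref_pos = pos.copy()

    def forces_energy():
        f = np.zeros_like(pos)
        w = np.zeros((3, 3))
        try:
            e = _kernels.nonbonded_kernel(
                pos, cfg.box, pairs, tid, tab.eps, tab.sigma, tab.lam, tab.nu,
                tab.amp, tab.cpi, tab.hyd_kind, tab.kappa, tab.rc_hyd_factor,
                tab.rc_elec, f, w,
            )
            e += _kernels.bond_kernel(
                pos, cfg.box, bonds, model.bond_k_nm, model.bond_r0_nm, f, w
            )
        except ZeroDivisionError:
            raise SimulationError("coincident beads: interparticle distance is zero")
        return e, f, w

    energy, forces, virial = forces_energy()

    traj = Trajectory()
    stress_rows = []
    energy_rows = []

    def snapshot_frame(time):
        frame = cfg.copy()
        frame.positions = pos.copy()
        frame.velocities = vel.copy()
        frame.wrap()
        traj.append(frame, time)

    def record(step, time):
        if settings.stress_stride and step % settings.stress_stride == 0:
            kin = (masses[:, None, None] * vel[:, :, None] * vel[:, None, :]).sum(axis=0)
            s = (kin + virial) / volume * PRESSURE_KJ_NM3_TO_BAR
            stress_rows.append(
                (time, s[0, 1], s[0, 2], s[1, 2], s[0, 0], s[1, 1], s[2, 2])
            )
        if settings.energy_stride and step % settings.energy_stride == 0:
            energy_rows.append(
                (time, energy, 0.5 * float(np.sum(masses[:, None] * vel**2)),
                 kinetic_temperature(vel, masses))
            )
        if settings.traj_stride and step % settings.traj_stride == 0 and step > 0:
            snapshot_frame(time)

    record(0, 0.0)
    if settings.n_steps == 0:
        # zero-step run: return the initial configuration unchanged
        frame = cfg.copy()
        frame.velocities = vel.copy()
        traj.append(frame, 0.0)

    half = 0.5 * dt / masses[:, None]
    for step in range(1, settings.n_steps + 1):
        vel += forces * half
        pos += 0.5 * dt * vel
        if settings.damping is not None:
            vel = c1 * vel + c2 * rng.normal(size=vel.shape)
        pos += 0.5 * dt * vel
        if _kernels.max_displacement(pos, ref_pos, cfg.box) > 0.5 * settings.skin:
            pos -= cfg.box * np.floor(pos / cfg.box)
            pairs = build_pairs()
            ref_pos = pos.copy()
        energy, forces, virial = forces_energy()
        if not np.isfinite(forces).all():
            raise SimulationError(f"non-finite forces at step {step}")
        vel += forces * half
        record(step, step * dt)

    if settings.n_steps > 0 and (
        not settings.traj_stride or settings.n_steps % settings.traj_stride != 0
    ):
        snapshot_frame(settings.n_steps * dt)

    stress = None
    if stress_rows:
        arr = np.array(stress_rows)
        stress = StressSeries(
            arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4], arr[:, 5], arr[:, 6],
            volume, settings.temperature,
        )
    energies = pd.DataFrame(
        energy_rows, columns=["t_ps", "potential", "kinetic", "temperature"]
    )
    return traj, stress, energies
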