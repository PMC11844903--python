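"""Synthetic reference data with known ground truth.

Everything here is generated, not measured: coexistence curves drawn from
the critical scaling laws, stress time series built from Ornstein-Uhlenbeck
(OU) processes whose relaxation modulus is known analytically, idealised
two-phase bead configurations, and a deliberately small toy force field.
Each generator is deterministic for a given seed and returns the ground
truth alongside the data so estimator tests never compare against tuned
numbers.

OU stress construction: the Green-Kubo estimator averages the three
off-diagonal stress autocorrelations plus one sixth of the three
normal-stress-difference autocorrelations.  For each Maxwell mode
(G_i, tau_i) the three off-diagonal components receive independent OU
processes with autocovariance c_i exp(-t/tau_i), and the three diagonal
components receive independent OU processes with autocovariance
2 c_i exp(-t/tau_i), so each normal difference contributes 4 c_i and the
combined estimator sees 3 c_i + (1/6)(3)(4 c_i) = 5 c_i.  With
c_i = G_i kB T / V (expressed in bar^2) the recovered modulus is exactly
sum_i G_i exp(-t/tau_i).
"""

from __future__ import annotations

import numpy as np

from .constants import KB, KCAL_TO_KJ, PRESSURE_KJ_NM3_TO_BAR
from .forcefield import ModelDefinition, ResidueParameters
from .phase import CoexistencePoint
from .rheology import StressSeries
from .system import Configuration, Trajectory


class SyntheticDataError(ValueError):
    pass


def _check_seed(seed: int) -> int:
    seed = int(seed)
    if not 0 <= seed < 2**31:
        raise SyntheticDataError("seed must lie in [0, 2^31)")
    return seed


def synthetic_coexistence_dataset(
    Tc: float = 320.0,
    rho_c: float = 0.12,
    s1: float = 0.02,
    s2: float = 5.0e-4,
    alpha: float = 3.06,
    temperatures: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[CoexistencePoint], dict]:
    """Coexistence points drawn exactly from the critical scaling laws.

    (rho_l - rho_v)^alpha = s1 (1 - T/Tc) and
    (rho_l + rho_v)/2 = rho_c + s2 (Tc - T); optional multiplicative
    Gaussian ``noise`` (relative standard deviation) perturbs both branch
    densities independently.
    """
    rng = np.random.default_rng(_check_seed(seed))
    if temperatures is None:
        temperatures = np.linspace(0.80 * Tc, 0.97 * Tc, 8)
    T = np.asarray(temperatures, dtype=float)
    if np.any(T >= Tc) or np.any(T <= 0):
        raise SyntheticDataError("temperatures must be positive and below Tc")
    drho = (s1 * (1.0 - T / Tc)) ** (1.0 / alpha)
    mid = rho_c + s2 * (Tc - T)
    rho_l = mid + 0.5 * drho
    rho_v = mid - 0.5 * drho
    if np.any(rho_v <= 0):
        raise SyntheticDataError(
            "parameters put the vapour branch below zero; reduce s1 or raise rho_c"
        )
    if noise:
        rho_l = rho_l * (1.0 + noise * rng.standard_normal(len(T)))
        rho_v = rho_v * (1.0 + noise * rng.standard_normal(len(T)))
        keep = rho_l > rho_v
        rho_l, rho_v, T = rho_l[keep], rho_v[keep], T[keep]
        if len(T) < 4:
            raise SyntheticDataError("noise destroyed too many points; lower it")
    points = [
        CoexistencePoint(float(t), float(l), float(max(v, 1e-9)))
        for t, l, v in zip(T, rho_l, rho_v)
    ]
    truth = {
        "Tc": Tc,
        "rho_c": rho_c,
        "s1": s1,
        "s2": s2,
        "alpha": alpha,
        "noise": noise,
        "seed": seed,
        "synthetic": True,
    }
    return points, truth


def _ou_series(rng, n: int, dt: float, tau: float, variance: float) -> np.ndarray:
    """Exactly discretised stationary OU path with autocovariance
    variance * exp(-t/tau)."""
    phi = np.exp(-dt / tau)
    x = np.empty(n)
    x[0] = np.sqrt(variance) * rng.standard_normal()
    innovations = np.sqrt(variance * (1.0 - phi * phi)) * rng.standard_normal(n - 1)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + innovations[k - 1]
    return x


def synthetic_stress_series(
    G_modes,
    tau_modes,
    volume: float = 1000.0,
    temperature: float = 300.0,
    dt: float = 1.0,
    n_samples: int = 2**17,
    seed: int = 0,
) -> tuple[StressSeries, dict]:
    """Stress tensor series whose relaxation modulus is a known Maxwell sum.

    ``G_modes`` in bar, ``tau_modes`` in ps, ``volume`` in nm^3.  The exact
    modulus is G(t) = sum_i G_i exp(-t/tau_i) and the exact zero-shear
    viscosity sum_i G_i tau_i (bar ps).
    """
    G_modes = np.asarray(G_modes, dtype=float)
    tau_modes = np.asarray(tau_modes, dtype=float)
    if len(G_modes) != len(tau_modes) or len(G_modes) == 0:
        raise SyntheticDataError("need matching, non-empty G and tau mode arrays")
    if np.any(G_modes <= 0) or np.any(tau_modes <= 0):
        raise SyntheticDataError("mode amplitudes and times must be positive")
    rng = np.random.default_rng(_check_seed(seed))
    # bar^2 autocovariance per mode reproducing G_i after the V/(5 kB T) factor
    c = G_modes * KB * temperature / volume * PRESSURE_KJ_NM3_TO_BAR
    comps = {k: np.zeros(n_samples) for k in ("sxy", "sxz", "syz", "sxx", "syy", "szz")}
    for ci, tau in zip(c, tau_modes):
        for k in ("sxy", "sxz", "syz"):
            comps[k] += _ou_series(rng, n_samples, dt, tau, ci)
        for k in ("sxx", "syy", "szz"):
            comps[k] += _ou_series(rng, n_samples, dt, tau, 2.0 * ci)
    times = np.arange(n_samples) * dt
    series = StressSeries(
        times,
        comps["sxy"],
        comps["sxz"],
        comps["syz"],
        comps["sxx"],
        comps["syy"],
        comps["szz"],
        volume,
        temperature,
    )
    truth = {
        "G_modes_bar": G_modes.tolist(),
        "tau_modes_ps": tau_modes.tolist(),
        "viscosity_bar_ps": float(np.dot(G_modes, tau_modes)),
        "seed": seed,
        "synthetic": True,
    }
    return series, truth


def synthetic_two_phase_frame(
    model: ModelDefinition,
    residue: str = "G",
    box=(10.0, 10.0, 60.0),
    rho_l: float = 0.30,
    rho_v: float = 0.01,
    slab_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Single-frame trajectory of uniform beads forming an ideal slab.

    Beads of one residue type are placed uniformly at mass density ``rho_l``
    (g/cm^3) inside a central slab covering ``slab_fraction`` of the box
    length and at ``rho_v`` outside; each bead is its own chain, so the
    frame carries no bonds.
    """
    if not 0 < slab_fraction < 1:
        raise SyntheticDataError("slab_fraction must lie in (0, 1)")
    if not rho_l > rho_v >= 0:
        raise SyntheticDataError("need rho_l > rho_v >= 0")
    rng = np.random.default_rng(_check_seed(seed))
    box = np.asarray(box, dtype=float)
    mass = model.residue_masses[residue]
    from .constants import MASS_DENSITY_TO_G_CM3

    Lz = box[2]
    slab = slab_fraction * Lz
    vol_dense = box[0] * box[1] * slab
    vol_dilute = box[0] * box[1] * (Lz - slab)
    n_dense = int(round(rho_l / MASS_DENSITY_TO_G_CM3 / mass * vol_dense))
    n_dilute = int(round(rho_v / MASS_DENSITY_TO_G_CM3 / mass * vol_dilute))
    if n_dense < 10:
        raise SyntheticDataError("dense slab holds fewer than 10 beads; enlarge the box")
    z0 = 0.5 * (Lz - slab)
    dense = rng.uniform(size=(n_dense, 3)) * np.array([box[0], box[1], slab])
    dense[:, 2] += z0
    dilute = rng.uniform(size=(n_dilute, 3)) * box
    # rejection: keep dilute beads outside the slab
    outside = (dilute[:, 2] < z0) | (dilute[:, 2] >= z0 + slab)
    while outside.sum() < n_dilute:
        extra = rng.uniform(size=(n_dilute, 3)) * box
        dilute = np.vstack([dilute[outside], extra])
        outside = (dilute[:, 2] < z0) | (dilute[:, 2] >= z0 + slab)
    dilute = dilute[outside][:n_dilute]
    pos = np.vstack([dense, dilute])
    n = len(pos)
    cfg = Configuration(
        positions=pos,
        box=box,
        chain_ids=np.arange(n),
        residues=np.full(n, residue, dtype="U1"),
    )
    traj = Trajectory()
    traj.append(cfg, 0.0)
    truth = {
        "rho_l": rho_l,
        "rho_v": rho_v,
        "slab_fraction": slab_fraction,
        "n_dense": n_dense,
        "n_dilute": n_dilute,
        "seed": seed,
        "synthetic": True,
    }
    return traj, truth


def toy_model(
    sticker_eps_kcal: float = 0.8,
    spacer_lambda: float = 0.1,
    sigma_nm: float = 0.45,
    mass: float = 100.0,
) -> ModelDefinition:
    """Minimal Ashbaugh-Hatch model for fast smoke tests (synthetic).

    Three bead types borrow canonical letters so sequence tooling applies:
    W is a maximally sticky bead (lambda = 1), G a weak spacer, and K/D a
    +1/-1 charge pair.  The epsilon is deliberately large so a 10-chain
    slab demixes within minutes of CPU time.
    """
    eps = sticker_eps_kcal * KCAL_TO_KJ
    residues = {
        "W": ResidueParameters("W", 0.0, 1.0, sigma_nm, mass),
        "G": ResidueParameters("G", 0.0, spacer_lambda, sigma_nm, mass),
        "K": ResidueParameters("K", 1.0, spacer_lambda, sigma_nm, mass),
        "D": ResidueParameters("D", -1.0, spacer_lambda, sigma_nm, mass),
    }
    return ModelDefinition(
        name="toy-synthetic",
        hydrophobic_scheme="ashbaugh_hatch",
        electrostatic_scheme="debye_huckel_fixed_kappa",
        residues=residues,
        bond_k=9.6,
        ah_epsilon=eps,
        kappa_fixed=1.0,
        epsilon_r_fixed=80.0,
        hyd_cutoff_sigma=3.0,
        elec_cutoff=2.0,
    )
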