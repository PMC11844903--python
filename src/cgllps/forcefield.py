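"""Residue-resolution coarse-grained force fields for disordered proteins.

Implements the potential-energy function

    E = E_bonds + E_electrostatic + E_hydrophobic + E_cation-pi

shared by six published one-bead-per-residue models (HPS, HPS-cation-pi,
HPS-Urry, CALVADOS2, Mpipi, Mpipi-Recharged).  Bonds are harmonic
(E = k (r - r0)^2, no 1/2 factor).  Hydrophobic interactions use either the
Ashbaugh-Hatch split Lennard-Jones form with Lorentz-Berthelot mixing, or
the pair-specific Wang-Frenkel potential.  Electrostatics are screened:
Debye-Hueckel (charge product) or a pair-amplitude Yukawa form.  The
HPS-cation-pi model adds an extra Lennard-Jones attraction between
arginine/lysine and aromatic residues.

Internal units: nm, kJ/mol, K, e.  Converters sit at the I/O boundaries
(bond constants are quoted per Angstrom^2, Ashbaugh-Hatch epsilon in
kcal/mol, as in the source publications).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .constants import COULOMB_KJ_NM, KB, KCAL_TO_KJ, MM_TO_PER_NM3
from .neighbors import pair_list
from .system import Configuration

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AROMATIC = set("FWY")
CATIONIC = set("RK")

MODEL_NAMES = (
    "HPS",
    "HPS-cation-pi",
    "HPS-Urry",
    "CALVADOS2",
    "Mpipi",
    "Mpipi-Recharged",
)


class ForceFieldError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scalar potential terms
# ---------------------------------------------------------------------------


def dielectric_of_temperature(T: float) -> float:
    """Relative permittivity of water from the empirical T-dependent law.

    Valid between 230 K and 450 K; strictly decreasing over that window.
    """
    if not 230.0 < T < 450.0:
        raise ForceFieldError(f"temperature {T} K outside the 230-450 K validity window")
    return 5321.0 / T + 233.76 - 0.9297 * T + 1.417e-3 * T**2 - 8.292e-7 * T**3


def bjerrum_length(T: float, eps_r: float) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kB T) in nm."""
    return COULOMB_KJ_NM / (eps_r * KB * T)


def debye_kappa(c_s: float, T: float, eps_r: float) -> float:
    """Inverse Debye screening length kappa = sqrt(8 pi B c_s) in nm^-1.

    ``c_s`` is the monovalent salt concentration in mM; it is converted to a
    number density in nm^-3 before entering the square root.
    """
    if c_s < 0:
        raise ForceFieldError("salt concentration must be non-negative")
    rho = c_s * MM_TO_PER_NM3
    return math.sqrt(8.0 * math.pi * bjerrum_length(T, eps_r) * rho)


def bond_energy(r: float, k: float = 9.6, r0: float = 3.81) -> float:
    """Harmonic bond energy k (r - r0)^2 with r, r0 in Angstrom and k in kJ/(mol A^2)."""
    if r <= 0:
        raise ForceFieldError("bond length must be positive")
    return k * (r - r0) ** 2


def ashbaugh_hatch_energy(r: float, eps: float, sigma: float, lam: float) -> float:
    """Ashbaugh-Hatch hydropathy-scaled Lennard-Jones potential (kJ/mol).

    For r below the LJ minimum 2^(1/6) sigma the full LJ is shifted up by
    (1 - lambda) eps; beyond it the LJ tail is scaled by lambda.  The two
    branches meet continuously at the split point with value -lambda eps.
    """
    if r <= 0:
        raise ForceFieldError("distance must be positive")
    sr6 = (sigma / r) ** 6
    ulj = 4.0 * eps * (sr6 * sr6 - sr6)
    if r < 2.0 ** (1.0 / 6.0) * sigma:
        return ulj + (1.0 - lam) * eps
    return lam * ulj


def wang_frenkel_alpha(nu: float, mu: float, rc_over_sigma: float) -> float:
    """Normaliser alpha making the Wang-Frenkel well depth exactly -eps."""
    x = rc_over_sigma ** (2.0 * mu)
    return 2.0 * nu * x * ((1.0 + 2.0 * nu) / (2.0 * nu * (x - 1.0))) ** (2.0 * nu + 1.0)


def wang_frenkel_energy(
    r: float,
    eps: float,
    sigma: float,
    nu: float,
    mu: float = 1.0,
    rc: float | None = None,
) -> float:
    """Wang-Frenkel pair potential (kJ/mol); zero at sigma and at rc = 3 sigma."""
    if r <= 0:
        raise ForceFieldError("distance must be positive")
    if rc is None:
        rc = 3.0 * sigma
    if r >= rc:
        return 0.0
    alpha = wang_frenkel_alpha(nu, mu, rc / sigma)
    s = (sigma / r) ** (2.0 * mu)
    c = (rc / r) ** (2.0 * mu)
    return eps * alpha * (s - 1.0) * (c - 1.0) ** (2.0 * nu)


def wang_frenkel_rmin(sigma: float, nu: float, mu: float = 1.0, rc: float | None = None) -> float:
    """Location of the Wang-Frenkel minimum."""
    if rc is None:
        rc = 3.0 * sigma
    x = (rc / sigma) ** (2.0 * mu)
    return rc * ((1.0 + 2.0 * nu) / (1.0 + 2.0 * nu * x)) ** (1.0 / (2.0 * mu))


def debye_huckel_energy(r: float, q_i: float, q_j: float, eps_r: float, kappa: float) -> float:
    """Screened Coulomb interaction between charges in e units (kJ/mol)."""
    if r <= 0:
        raise ForceFieldError("distance must be positive")
    return COULOMB_KJ_NM * q_i * q_j / eps_r * math.exp(-kappa * r) / r


def yukawa_energy(r: float, A_ij: float, kappa: float) -> float:
    """Yukawa potential A_ij exp(-kappa r) / r with A_ij in kJ nm / mol."""
    if r <= 0:
        raise ForceFieldError("distance must be positive")
    return A_ij * math.exp(-kappa * r) / r


def cation_pi_energy(r: float, eps: float, sigma: float, pair: tuple[str, str]) -> float:
    """Extra cation-pi Lennard-Jones term between R/K and F/W/Y beads."""
    a, b = pair
    if not (
        (a in CATIONIC and b in AROMATIC) or (b in CATIONIC and a in AROMATIC)
    ):
        raise ForceFieldError(f"cation-pi term does not apply to pair {pair}")
    if r <= 0:
        raise ForceFieldError("distance must be positive")
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueParameters:
    code: str
    charge: float  # e
    hydropathy: float  # dimensionless lambda
    sigma: float  # nm
    mass: float  # g/mol

    def __post_init__(self):
        if self.sigma <= 0 or self.mass <= 0:
            raise ForceFieldError(f"residue {self.code}: sigma and mass must be positive")


@dataclass(frozen=True)
class PairCoefficients:
    eps: float  # kJ/mol
    sigma: float  # nm
    lam: float = 0.0
    nu: float = 1.0
    yukawa_A: float = 0.0  # kJ nm / mol
    cation_pi_eps: float = 0.0  # kJ/mol


@dataclass
class ParamTables:
    """Numeric per-type-pair tables consumed by the numba kernel."""

    codes: list[str]
    eps: np.ndarray
    sigma: np.ndarray
    lam: np.ndarray
    nu: np.ndarray
    amp: np.ndarray  # full electrostatic amplitude (kJ nm / mol)
    cpi: np.ndarray
    hyd_kind: int
    kappa: float
    rc_hyd_factor: float
    rc_elec: float
    masses: np.ndarray

    def type_ids(self, residues: np.ndarray) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.codes)}
        try:
            return np.array([index[str(r)] for r in residues], dtype=np.int64)
        except KeyError as exc:
            raise ForceFieldError(f"unknown residue code {exc.args[0]!r}") from None

    @property
    def max_cutoff(self) -> float:
        return max(self.rc_elec, self.rc_hyd_factor * float(self.sigma.max()))


@dataclass
class ModelDefinition:
    """Which potentials, constants, and cutoffs a named model uses."""

    name: str
    hydrophobic_scheme: str  # ashbaugh_hatch | wang_frenkel
    electrostatic_scheme: str  # debye_huckel_fixed_kappa | debye_huckel_salt_T | yukawa
    residues: dict[str, ResidueParameters]
    bond_k: float = 9.6  # kJ/(mol A^2)
    bond_r0: float = 3.81  # A
    ah_epsilon: float = 0.2 * KCAL_TO_KJ  # kJ/mol, Ashbaugh-Hatch pair epsilon
    kappa_fixed: float | None = 1.0  # nm^-1 (None -> derived from salt and T)
    salt_mM: float = 150.0
    epsilon_r_fixed: float | None = 80.0  # None -> temperature-dependent law
    hyd_cutoff_sigma: float = 3.0  # r_c as a multiple of sigma_ij
    elec_cutoff: float = 3.5  # nm
    wf_pairs: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    yukawa_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    cation_pi_eps: dict[tuple[str, str], float] = field(default_factory=dict)
    mu: float = 1.0

    # -- derived quantities -------------------------------------------------
    @property
    def bond_k_nm(self) -> float:
        return self.bond_k * 100.0  # kJ/(mol A^2) -> kJ/(mol nm^2)

    @property
    def bond_r0_nm(self) -> float:
        return self.bond_r0 / 10.0

    def epsilon_r(self, T: float) -> float:
        if self.epsilon_r_fixed is not None:
            return self.epsilon_r_fixed
        return dielectric_of_temperature(T)

    def kappa(self, T: float) -> float:
        if self.kappa_fixed is not None:
            return self.kappa_fixed
        return debye_kappa(self.salt_mM, T, self.epsilon_r(T))

    @property
    def residue_masses(self) -> dict[str, float]:
        return {c: p.mass for c, p in self.residues.items()}

    def pair_coefficients(self, i: str, j: str) -> PairCoefficients:
        a, b = self.residues[i], self.residues[j]
        sigma = 0.5 * (a.sigma + b.sigma)
        cpi = self.cation_pi_eps.get((i, j)) or self.cation_pi_eps.get((j, i)) or 0.0
        if self.hydrophobic_scheme == "ashbaugh_hatch":
            lam = 0.5 * (a.hydropathy + b.hydropathy)
            eps, nu = self.ah_epsilon, 1.0
        else:
            rec = self.wf_pairs.get((i, j)) or self.wf_pairs.get((j, i))
            if rec is None:
                raise ForceFieldError(f"{self.name}: missing pair coefficients for {i}-{j}")
            eps, sigma, nu = rec
            lam = 0.0
        A = 0.0
        if self.electrostatic_scheme == "yukawa":
            A = self.yukawa_pairs.get((i, j)) or self.yukawa_pairs.get((j, i)) or 0.0
        return PairCoefficients(eps, sigma, lam, nu, A, cpi)

    def tables(self, T: float) -> ParamTables:
        codes = sorted(self.residues)
        n = len(codes)
        eps = np.zeros((n, n))
        sig = np.zeros((n, n))
        lam = np.zeros((n, n))
        nu = np.ones((n, n))
        amp = np.zeros((n, n))
        cpi = np.zeros((n, n))
        eps_r = self.epsilon_r(T)
        for ii, ci in enumerate(codes):
            for jj, cj in enumerate(codes):
                pc = self.pair_coefficients(ci, cj)
                eps[ii, jj] = pc.eps
                sig[ii, jj] = pc.sigma
                lam[ii, jj] = pc.lam
                nu[ii, jj] = pc.nu
                cpi[ii, jj] = pc.cation_pi_eps
                if self.electrostatic_scheme == "yukawa":
                    amp[ii, jj] = pc.yukawa_A
                else:
                    qq = self.residues[ci].charge * self.residues[cj].charge
                    amp[ii, jj] = COULOMB_KJ_NM * qq / eps_r
        hyd_kind = (
            _kernels.HYD_ASHBAUGH_HATCH
            if self.hydrophobic_scheme == "ashbaugh_hatch"
            else _kernels.HYD_WANG_FRENKEL
        )
        masses = np.array([self.residues[c].mass for c in codes])
        return ParamTables(
            codes=codes,
            eps=eps,
            sigma=sig,
            lam=lam,
            nu=nu,
            amp=amp,
            cpi=cpi,
            hyd_kind=hyd_kind,
            kappa=self.kappa(T),
            rc_hyd_factor=self.hyd_cutoff_sigma,
            rc_elec=self.elec_cutoff,
            masses=masses,
        )

    def validate(self, alphabet: str | None = None) -> None:
        """Check table completeness and symmetry for the model's alphabet."""
        alphabet = alphabet or "".join(sorted(self.residues))
        missing = [c for c in alphabet if c not in self.residues]
        if missing:
            raise ForceFieldError(f"{self.name}: missing residues {missing}")
        if self.hydrophobic_scheme == "wang_frenkel":
            missing_pairs = [
                (i, j)
                for k, i in enumerate(alphabet)
                for j in alphabet[k:]
                if (i, j) not in self.wf_pairs and (j, i) not in self.wf_pairs
            ]
            if missing_pairs:
                raise ForceFieldError(
                    f"{self.name}: missing pair coefficients for {missing_pairs[:5]}..."
                    if len(missing_pairs) > 5
                    else f"{self.name}: missing pair coefficients for {missing_pairs}"
                )
        if self.hyd_cutoff_sigma <= 0 or self.elec_cutoff <= 0:
            raise ForceFieldError("cutoffs must be positive")


# ---------------------------------------------------------------------------
# model loading from packaged parameter files
# ---------------------------------------------------------------------------


def _data_dir() -> Path:
    return Path(str(importlib.resources.files("cgllps"))) / "data" / "models"


def _read_residue_table(path: Path) -> dict[str, ResidueParameters]:
    df = pd.read_csv(path, comment="#")
    out = {}
    for _, row in df.iterrows():
        out[row["residue"]] = ResidueParameters(
            code=row["residue"],
            charge=float(row["q"]),
            hydropathy=float(row["lambda"]),
            sigma=float(row["sigma_nm"]),
            mass=float(row["mass"]),
        )
    return out


def _read_pair_table(path: Path) -> dict[tuple[str, str], tuple[float, float, float]]:
    df = pd.read_csv(path, comment="#")
    return {
        (row["i"], row["j"]): (float(row["eps_kj"]), float(row["sigma_nm"]), float(row["nu"]))
        for _, row in df.iterrows()
    }


def _read_yukawa_table(path: Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, comment="#")
    return {(row["i"], row["j"]): float(row["A_kj_nm"]) for _, row in df.iterrows()}


def _read_cation_pi_table(path: Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, comment="#")
    return {(row["i"], row["j"]): float(row["eps_kj"]) for _, row in df.iterrows()}


def normalize_model_name(name: str) -> str:
    key = name.replace("π", "pi").replace("π", "pi").lower().replace("_", "-")
    for canonical in MODEL_NAMES:
        if key == canonical.lower():
            return canonical
    raise ForceFieldError(
        f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
    )


def load_model(name: str, parameter_dir: str | Path | None = None) -> ModelDefinition:
    """Load one of the six packaged models from its parameter files."""
    name = normalize_model_name(name)
    data = Path(parameter_dir) if parameter_dir else _data_dir()
    registry = yaml.safe_load((data / "registry.yaml").read_text())["models"]
    entry = registry[name]
    residues = _read_residue_table(data / entry["residues"])
    model = ModelDefinition(
        name=name,
        hydrophobic_scheme=entry["hydrophobic"],
        electrostatic_scheme=entry["electrostatic"],
        residues=residues,
        bond_k=float(entry["bond_k_kj_A2"]),
        bond_r0=float(entry.get("bond_r0_A", 3.81)),
        ah_epsilon=float(entry.get("ah_epsilon_kcal", 0.2)) * KCAL_TO_KJ,
        kappa_fixed=entry.get("kappa_nm_inv"),
        salt_mM=float(entry.get("salt_mM", 150.0)),
        epsilon_r_fixed=entry.get("epsilon_r"),
        hyd_cutoff_sigma=float(entry.get("hyd_cutoff_sigma", 3.0)),
        elec_cutoff=float(entry["elec_cutoff_nm"]),
        wf_pairs=_read_pair_table(data / entry["pairs"]) if "pairs" in entry else {},
        yukawa_pairs=_read_yukawa_table(data / entry["yukawa"]) if "yukawa" in entry else {},
        cation_pi_eps=(
            _read_cation_pi_table(data / entry["cation_pi"]) if "cation_pi" in entry else {}
        ),
    )
    model.validate(CANONICAL_RESIDUES)
    return model


# ---------------------------------------------------------------------------
# total energy / forces
# ---------------------------------------------------------------------------


def total_energy_forces(
    model: ModelDefinition,
    configuration: Configuration,
    T: float = 298.0,
    tables: ParamTables | None = None,
    pairs: np.ndarray | None = None,
    return_virial: bool = False,
):
    """Total potential energy and per-bead forces (exact negative gradients).

    Nonbonded terms use the minimum-image convention; bonded 1-2 pairs are
    excluded from the nonbonded sums.
    """
    tab = tables if tables is not None else model.tables(T)
    tid = tab.type_ids(configuration.residues)
    bonds = configuration.bonds()
    if pairs is None:
        pairs = pair_list(
            configuration.positions, configuration.box, tab.max_cutoff, exclude=bonds
        )
    forces = np.zeros_like(configuration.positions)
    virial = np.zeros((3, 3))
    energy = _kernels.nonbonded_kernel(
        configuration.positions,
        configuration.box,
        pairs,
        tid,
        tab.eps,
        tab.sigma,
        tab.lam,
        tab.nu,
        tab.amp,
        tab.cpi,
        tab.hyd_kind,
        tab.kappa,
        tab.rc_hyd_factor,
        tab.rc_elec,
        forces,
        virial,
    )
    energy += _kernels.bond_kernel(
        configuration.positions,
        configuration.box,
        bonds,
        model.bond_k_nm,
        model.bond_r0_nm,
        forces,
        virial,
    )
    if return_virial:
        return energy, forces, virial
    return energy, forces


# ---------------------------------------------------------------------------
# interaction-strength matrices
# ---------------------------------------------------------------------------


def interaction_strength_matrix(
    model: ModelDefinition, T: float = 298.0
) -> pd.DataFrame:
    """Normalised per-type-pair interaction strengths.

    For each type pair the hydrophobic well depth (plus any cation-pi term)
    and the screened electrostatic energy evaluated at the pair's potential
    minimum distance are summed; the sign is flipped so attraction is
    positive, and the matrix is divided by its largest-magnitude entry.
    """
    codes = sorted(model.residues)
    eps_r = model.epsilon_r(T)
    kappa = model.kappa(T)
    n = len(codes)
    m = np.zeros((n, n))
    for a, ci in enumerate(codes):
        for b in range(a, n):
            cj = codes[b]
            pc = model.pair_coefficients(ci, cj)
            if model.hydrophobic_scheme == "ashbaugh_hatch":
                rmin = 2.0 ** (1.0 / 6.0) * pc.sigma
                e_hyd = -pc.lam * pc.eps
            else:
                rmin = wang_frenkel_rmin(pc.sigma, pc.nu, model.mu, model.hyd_cutoff_sigma * pc.sigma)
                e_hyd = -pc.eps
            e_cpi = -pc.cation_pi_eps
            if model.electrostatic_scheme == "yukawa":
                e_el = yukawa_energy(rmin, pc.yukawa_A, kappa)
            else:
                qq = model.residues[ci].charge * model.residues[cj].charge
                e_el = debye_huckel_energy(rmin, 1.0, qq, eps_r, kappa)
            m[a, b] = m[b, a] = -(e_hyd + e_cpi + e_el)
    peak = np.abs(m).max()
    if peak > 0:
        m = m / peak
    return pd.DataFrame(m, index=list(codes), columns=list(codes))
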