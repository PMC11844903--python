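"""Intermolecular contact statistics and pairwise interaction rankings.

A contact is an intermolecular bead pair closer than 1.2 sigma_ij, with
sigma_ij the Lorentz-Berthelot pair diameter.  Frequencies are averaged
over frames and reported per residue-type pair.  The energy-weighted
interaction strength of a type pair combines its contact frequency with
the hydrophobic plus electrostatic pair energy at the typical contact
distance, normalised per residue abundance,

    S_ij = f_ij * (E_hyd(r_ij) + E_elec(r_ij)) / (N_i N_j),

then scaled so the strongest (most negative-energy, i.e. largest) entry
is one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .forcefield import (
    ModelDefinition,
    ashbaugh_hatch_energy,
    debye_huckel_energy,
    wang_frenkel_energy,
    yukawa_energy,
    cation_pi_energy,
    AROMATIC,
    CATIONIC,
)
from .system import Configuration, Trajectory


class ContactAnalysisError(ValueError):
    pass


@dataclass
class ContactMap:
    """Per-type-pair contact statistics accumulated over a trajectory."""

    codes: list[str]
    counts: np.ndarray  # mean intermolecular contacts per frame, (n, n)
    mean_distance: np.ndarray  # nm, contact-averaged; nan where no contacts
    n_frames: int
    cutoff_factor: float
    metadata: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.codes, columns=self.codes)


def _contact_pairs(cfg: Configuration, cutoff: float) -> np.ndarray:
    pos = cfg.positions % cfg.box
    pos = np.where(pos >= cfg.box, 0.0, pos)
    if cutoff < 0.5 * cfg.box.min():
        tree = cKDTree(pos, boxsize=cfg.box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
    else:
        n = cfg.n_beads
        ii, jj = np.triu_indices(n, k=1)
        d = pos[ii] - pos[jj]
        d -= cfg.box * np.round(d / cfg.box)
        sel = np.einsum("ij,ij->i", d, d) < cutoff * cutoff
        pairs = np.column_stack([ii[sel], jj[sel]])
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    # intermolecular only
    return pairs[cfg.chain_ids[pairs[:, 0]] != cfg.chain_ids[pairs[:, 1]]]


def intermolecular_contact_frequencies(
    trajectory: Trajectory,
    model: ModelDefinition,
    cutoff_factor: float = 1.2,
    temperature: float | None = None,
) -> ContactMap:
    """Mean per-frame intermolecular contact counts per residue-type pair.

    The candidate search uses the largest pair cutoff; each candidate pair
    is then tested against its own 1.2 sigma_ij threshold.
    """
    if len(trajectory) == 0:
        raise ContactAnalysisError("trajectory holds no frames")
    tab = model.tables(temperature if temperature is not None else 298.0)
    codes = tab.codes
    n_types = len(codes)
    sig = tab.sigma
    max_cut = cutoff_factor * float(sig.max())
    counts = np.zeros((n_types, n_types))
    dist_sum = np.zeros((n_types, n_types))
    for cfg in trajectory:
        tid = tab.type_ids(cfg.residues)
        pairs = _contact_pairs(cfg, max_cut)
        if len(pairs) == 0:
            continue
        d = cfg.positions[pairs[:, 0]] - cfg.positions[pairs[:, 1]]
        d -= cfg.box * np.round(d / cfg.box)
        r = np.linalg.norm(d, axis=1)
        ti, tj = tid[pairs[:, 0]], tid[pairs[:, 1]]
        sel = r < cutoff_factor * sig[ti, tj]
        ti, tj, r = ti[sel], tj[sel], r[sel]
        np.add.at(counts, (ti, tj), 1.0)
        np.add.at(counts, (tj, ti), 1.0)
        np.add.at(dist_sum, (ti, tj), r)
        np.add.at(dist_sum, (tj, ti), r)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dist = np.where(counts > 0, dist_sum / counts, np.nan)
    counts /= len(trajectory)
    return ContactMap(
        codes=list(codes),
        counts=counts,
        mean_distance=mean_dist,
        n_frames=len(trajectory),
        cutoff_factor=cutoff_factor,
        metadata={"temperature": temperature},
    )


def _pair_energy(model: ModelDefinition, ci: str, cj: str, r: float, T: float) -> float:
    """Hydrophobic + electrostatic (+ cation-pi) pair energy at distance r (kJ/mol)."""
    pc = model.pair_coefficients(ci, cj)
    if model.hydrophobic_scheme == "ashbaugh_hatch":
        e = ashbaugh_hatch_energy(r, pc.eps, pc.sigma, pc.lam)
    else:
        e = wang_frenkel_energy(
            r, pc.eps, pc.sigma, pc.nu, model.mu, model.hyd_cutoff_sigma * pc.sigma
        )
    if pc.cation_pi_eps > 0 and (
        (ci in CATIONIC and cj in AROMATIC) or (cj in CATIONIC and ci in AROMATIC)
    ):
        e += cation_pi_energy(r, pc.cation_pi_eps, pc.sigma, (ci, cj))
    if r <= model.elec_cutoff:
        if model.electrostatic_scheme == "yukawa":
            e += yukawa_energy(r, pc.yukawa_A, model.kappa(T))
        else:
            qq = model.residues[ci].charge * model.residues[cj].charge
            e += debye_huckel_energy(r, 1.0, qq, model.epsilon_r(T), model.kappa(T))
    return e


def contact_energy_map(
    contact_map: ContactMap,
    model: ModelDefinition,
    temperature: float = 298.0,
) -> pd.DataFrame:
    """Pair energies (kJ/mol) evaluated at each pair's observed mean contact
    distance; nan where the pair was never in contact."""
    n = len(contact_map.codes)
    e = np.full((n, n), np.nan)
    for a, ci in enumerate(contact_map.codes):
        for b in range(a, n):
            cj = contact_map.codes[b]
            r = contact_map.mean_distance[a, b]
            if np.isfinite(r) and r > 0:
                e[a, b] = e[b, a] = _pair_energy(model, ci, cj, float(r), temperature)
    return pd.DataFrame(e, index=contact_map.codes, columns=contact_map.codes)


def ranked_pair_interactions(
    contact_map: ContactMap,
    model: ModelDefinition,
    residue_counts: dict[str, int],
    temperature: float = 298.0,
    top: int | None = None,
) -> pd.DataFrame:
    """Energy-weighted contact strengths S_ij, normalised to a maximum of one.

    ``residue_counts`` gives per-type abundances N_i in the simulated system;
    frequencies are divided by N_i N_j so rare but sticky pairs rank fairly.
    Returned sorted by descending strength; attraction is positive.
    """
    codes = contact_map.codes
    energies = contact_energy_map(contact_map, model, temperature)
    rows = []
    for a, ci in enumerate(codes):
        for b in range(a, len(codes)):
            cj = codes[b]
            f = contact_map.counts[a, b]
            if f <= 0:
                continue
            n_i = residue_counts.get(ci, 0)
            n_j = residue_counts.get(cj, 0)
            if n_i == 0 or n_j == 0:
                raise ContactAnalysisError(
                    f"contacts observed for pair {ci}-{cj} but residue counts say zero"
                )
            e = energies.loc[ci, cj]
            # attraction (negative energy) counts as positive strength
            s = f * (-e) / (n_i * n_j)
            rows.append(
                {
                    "pair": f"{ci}-{cj}",
                    "frequency": f,
                    "energy_kj_mol": e,
                    "strength": s,
                }
            )
    if not rows:
        raise ContactAnalysisError("no contacts observed; cannot rank pairs")
    df = pd.DataFrame(rows)
    peak = df["strength"].abs().max()
    if peak > 0:
        df["strength"] = df["strength"] / peak
    df = df.sort_values("strength", ascending=False, ignore_index=True)
    return df.head(top) if top else df


def residue_abundances(cfg: Configuration) -> dict[str, int]:
    """Per-type bead counts of a configuration."""
    codes, counts = np.unique(cfg.residues, return_counts=True)
    return {str(c): int(k) for c, k in zip(codes, counts)}
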