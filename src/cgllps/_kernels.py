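"""Numba kernels for pairwise energies, forces and virials.

All kernels work in internal units (nm, kJ/mol, e) and use the
minimum-image convention in an orthorhombic periodic box.  Pair tables are
indexed by integer residue-type ids; the hydrophobic functional form is
selected by an integer flag (0 = Ashbaugh-Hatch, 1 = Wang-Frenkel) so a
single kernel serves every model.
"""

import numpy as np
from numba import njit

HYD_ASHBAUGH_HATCH = 0
HYD_WANG_FRENKEL = 1


@njit(cache=True, fastmath=False)
def _min_image(dx, dy, dz, box):
    dx -= box[0] * np.rint(dx / box[0])
    dy -= box[1] * np.rint(dy / box[1])
    dz -= box[2] * np.rint(dz / box[2])
    return dx, dy, dz


@njit(cache=True)
def nonbonded_kernel(
    pos,
    box,
    pairs,
    tid,
    eps_tab,
    sig_tab,
    lam_tab,
    nu_tab,
    amp_tab,
    cpi_tab,
    hyd_kind,
    kappa,
    rc_hyd_factor,
    rc_elec,
    forces,
    virial,
):
    """Accumulate nonbonded energy, forces, and virial over a pair list.

    ``amp_tab`` carries the full screened-electrostatic amplitude
    (Coulomb prefactor x charges / eps_r for Debye-Hueckel, or the pair
    amplitude A_ij for Yukawa), so the electrostatic term is always
    amp * exp(-kappa r) / r.  ``cpi_tab`` holds the extra cation-pi
    Lennard-Jones epsilon (zero where the term does not apply).
    """
    energy = 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, box)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        ti = tid[i]
        tj = tid[j]
        sig = sig_tab[ti, tj]
        rc_h = rc_hyd_factor * sig
        e = 0.0
        dudr = 0.0
        # hydrophobic / excluded volume
        if r < rc_h:
            epsv = eps_tab[ti, tj]
            if hyd_kind == HYD_ASHBAUGH_HATCH:
                lam = lam_tab[ti, tj]
                sr2 = (sig / r) ** 2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                ulj = 4.0 * epsv * (sr12 - sr6)
                dulj = 4.0 * epsv * (-12.0 * sr12 + 6.0 * sr6) / r
                if r < 1.122462048309373 * sig:
                    e += ulj + (1.0 - lam) * epsv
                    dudr += dulj
                else:
                    e += lam * ulj
                    dudr += lam * dulj
            else:
                nu = nu_tab[ti, tj]
                rcs2 = rc_hyd_factor * rc_hyd_factor
                two_nu = 2.0 * nu
                alpha = (
                    two_nu
                    * rcs2
                    * ((1.0 + two_nu) / (two_nu * (rcs2 - 1.0))) ** (two_nu + 1.0)
                )
                s2 = (sig / r) ** 2
                c2 = (rc_h / r) ** 2
                b = c2 - 1.0
                e += epsv * alpha * (s2 - 1.0) * b**two_nu
                dudr += (
                    epsv
                    * alpha
                    * (
                        (-2.0 * s2 / r) * b**two_nu
                        + (s2 - 1.0) * two_nu * b ** (two_nu - 1.0) * (-2.0 * c2 / r)
                    )
                )
            # extra cation-pi Lennard-Jones term (HPS-cation-pi only)
            ecp = cpi_tab[ti, tj]
            if ecp > 0.0:
                sr2 = (sig / r) ** 2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                e += 4.0 * ecp * (sr12 - sr6)
                dudr += 4.0 * ecp * (-12.0 * sr12 + 6.0 * sr6) / r
        # screened electrostatics
        if r < rc_elec:
            amp = amp_tab[ti, tj]
            if amp != 0.0:
                ex = np.exp(-kappa * r)
                e += amp * ex / r
                dudr += -amp * ex * (kappa * r + 1.0) / r2
        if e != 0.0 or dudr != 0.0:
            energy += e
            fmag = -dudr / r  # force = fmag * (ri - rj)
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            virial[0, 0] += fx * dx
            virial[0, 1] += fx * dy
            virial[0, 2] += fx * dz
            virial[1, 0] += fy * dx
            virial[1, 1] += fy * dy
            virial[1, 2] += fy * dz
            virial[2, 0] += fz * dx
            virial[2, 1] += fz * dy
            virial[2, 2] += fz * dz
    return energy


@njit(cache=True)
def bond_kernel(pos, box, bonds, k, r0, forces, virial):
    """Harmonic bonds E = k (r - r0)^2 (no 1/2 factor)."""
    energy = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        energy += k * (r - r0) ** 2
        dudr = 2.0 * k * (r - r0)
        fmag = -dudr / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += fx * dx
        virial[0, 1] += fx * dy
        virial[0, 2] += fx * dz
        virial[1, 0] += fy * dx
        virial[1, 1] += fy * dy
        virial[1, 2] += fy * dz
        virial[2, 0] += fz * dx
        virial[2, 1] += fz * dy
        virial[2, 2] += fz * dz
    return energy


@njit(cache=True)
def max_displacement(pos, ref, box):
    """Largest minimum-image displacement since the last neighbour build."""
    dmax2 = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        dx, dy, dz = _min_image(dx, dy, dz, box)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > dmax2:
            dmax2 = d2
    return np.sqrt(dmax2)
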