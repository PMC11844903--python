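"""Regenerate the packaged model parameter tables under src/cgllps/data/models.

Single-residue scalar tables (hydropathy scales, bead diameters, charges,
masses) are transcribed from the cited model publications.  The
Wang-Frenkel pair tables and Yukawa amplitude table for the Mpipi family,
and the extra cation-pi epsilon, are synthetic stand-ins built from the
documented rules below: the original fitted tables are distributed with the
model publications and are not reproduced here.  The stand-ins preserve the
qualitative structure those models are known for (aromatic ranking
W > Y > F, cation-pi with R stronger than K, pair-specific Yukawa
amplitudes that are symmetric in i<->j but not reducible to a product of
single-residue charges).
"""

from pathlib import Path

import yaml

OUT = Path(__file__).resolve().parent.parent / "src" / "cgllps" / "data" / "models"

RES = "ACDEFGHIKLMNPQRSTVWY"

MASS = {  # average residue masses, g/mol
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

SIGMA = {  # bead diameters, nm
    "A": 0.504, "R": 0.656, "N": 0.568, "D": 0.558, "C": 0.548, "Q": 0.602,
    "E": 0.592, "G": 0.450, "H": 0.608, "I": 0.618, "L": 0.618, "K": 0.636,
    "M": 0.618, "F": 0.636, "P": 0.556, "S": 0.518, "T": 0.562, "W": 0.678,
    "Y": 0.646, "V": 0.586,
}

CHARGE = {c: 0.0 for c in RES}
CHARGE.update({"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0})

LAMBDA_KR = {  # Kapcha-Rossky hydropathy scale (HPS, HPS-cation-pi)
    "A": 0.730, "R": 0.000, "N": 0.432, "D": 0.378, "C": 0.595, "Q": 0.514,
    "E": 0.459, "G": 0.649, "H": 0.514, "I": 0.973, "L": 0.973, "K": 0.514,
    "M": 0.838, "F": 1.000, "P": 1.000, "S": 0.595, "T": 0.676, "W": 0.946,
    "Y": 0.865, "V": 0.892,
}

LAMBDA_URRY = {  # shifted Urry hydropathy scale (HPS-Urry)
    "A": 0.602942, "R": 0.558824, "N": 0.588236, "D": 0.294118, "C": 0.647059,
    "Q": 0.558824, "E": 0.000000, "G": 0.573530, "H": 0.764707, "I": 0.705883,
    "L": 0.720589, "K": 0.382353, "M": 0.676471, "F": 0.823530, "P": 0.758824,
    "S": 0.588236, "T": 0.588236, "W": 1.000000, "Y": 0.897059, "V": 0.664706,
}

LAMBDA_CALVADOS2 = {  # Bayesian-optimised stickiness scale (CALVADOS2)
    "A": 0.2743, "R": 0.7307, "N": 0.4255, "D": 0.0416, "C": 0.5615,
    "Q": 0.3934, "E": 0.0006, "G": 0.7058, "H": 0.4663, "I": 0.5423,
    "L": 0.6440, "K": 0.1790, "M": 0.5308, "F": 0.8672, "P": 0.3593,
    "S": 0.4625, "T": 0.3713, "W": 0.9893, "Y": 0.9774, "V": 0.2083,
}

AROMATIC = "FWY"
CATIONIC = "RK"


def write_residue_csv(name, lam, charge, header):
    lines = [f"# {h}" for h in header]
    lines.append("residue,q,lambda,sigma_nm,mass")
    for c in RES:
        lines.append(f"{c},{charge[c]},{lam[c]},{SIGMA[c]},{MASS[c]}")
    (OUT / name).write_text("\n".join(lines) + "\n")


def build_wf_pairs(base_eps, aromatic_boost, r_boost, k_boost):
    """Synthetic Wang-Frenkel pair table: Urry-ranked baseline plus
    aromatic-aromatic and cation-aromatic boosts; sigma by arithmetic mean;
    nu = 1 throughout."""
    rows = []
    for a, i in enumerate(RES):
        for j in RES[a:]:
            eps = base_eps * 0.5 * (LAMBDA_URRY[i] + LAMBDA_URRY[j])
            if i in AROMATIC and j in AROMATIC:
                eps *= aromatic_boost
            elif (i == "R" and j in AROMATIC) or (j == "R" and i in AROMATIC):
                eps *= r_boost
            elif (i == "K" and j in AROMATIC) or (j == "K" and i in AROMATIC):
                eps *= k_boost
            sigma = 0.5 * (SIGMA[i] + SIGMA[j])
            rows.append((i, j, round(eps, 6), round(sigma, 4), 1.0))
    return rows


def write_pair_csv(name, rows, header):
    lines = [f"# {h}" for h in header]
    lines.append("i,j,eps_kj,sigma_nm,nu")
    for i, j, e, s, nu in rows:
        lines.append(f"{i},{j},{e},{s},{nu}")
    (OUT / name).write_text("\n".join(lines) + "\n")


def build_yukawa():
    """Synthetic pair-specific Yukawa amplitudes (kJ nm / mol): screened
    Coulomb scale at eps_r(298 K) with a like/unlike-sign asymmetry factor,
    so A_ij is i<->j symmetric but not a product of per-residue charges."""
    eps_r_298 = 5321.0 / 298.0 + 233.76 - 0.9297 * 298.0 + 1.417e-3 * 298.0**2 - 8.292e-7 * 298.0**3
    ke = 138.935458
    rows = []
    for a, i in enumerate(RES):
        for j in RES[a:]:
            qq = CHARGE[i] * CHARGE[j]
            if qq == 0.0:
                continue
            factor = 0.9 if qq > 0 else 0.75
            A = ke / eps_r_298 * qq * factor
            rows.append((i, j, round(A, 6)))
    return rows


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    write_residue_csv(
        "hps_residues.csv", LAMBDA_KR, CHARGE,
        ["HPS residue parameters: Kapcha-Rossky hydropathy scale, transcribed from the",
         "HPS model publication. Charges in e, sigma in nm, masses in g/mol."],
    )
    write_residue_csv(
        "hps_urry_residues.csv", LAMBDA_URRY, CHARGE,
        ["HPS-Urry residue parameters: shifted Urry hydropathy scale, transcribed from",
         "the HPS-Urry model publication."],
    )
    write_residue_csv(
        "calvados2_residues.csv", LAMBDA_CALVADOS2, CHARGE,
        ["CALVADOS2 residue parameters: Bayesian-optimised stickiness scale,",
         "transcribed from the CALVADOS2 model publication."],
    )
    mpipi_charge = {c: 0.0 for c in RES}
    mpipi_charge.update({"R": 0.75, "K": 0.75, "D": -0.75, "E": -0.75, "H": 0.375})
    write_residue_csv(
        "mpipi_residues_synthetic.csv", {c: 0.0 for c in RES}, mpipi_charge,
        ["Mpipi residue table (charges scaled to +-0.75, H +0.375 as in the model",
         "publication; lambda unused for Wang-Frenkel models). SYNTHETIC STAND-IN:",
         "sigma/mass shared with the HPS table."],
    )
    write_residue_csv(
        "mpipi_recharged_residues_synthetic.csv", {c: 0.0 for c in RES}, CHARGE,
        ["Mpipi-Recharged residue table (full formal charges listed for reference;",
         "electrostatics use the pair-specific Yukawa amplitude table). SYNTHETIC",
         "STAND-IN: sigma/mass shared with the HPS table."],
    )

    wf_header = [
        "SYNTHETIC STAND-IN Wang-Frenkel pair table (not the published fit).",
        "eps_ij = 0.85 kJ/mol * mean Urry lambda, x2.4 aromatic-aromatic,",
        "x{R} R-aromatic, x{K} K-aromatic; sigma_ij = mean bead diameter; nu = 1.",
    ]
    write_pair_csv(
        "mpipi_pairs_synthetic.csv",
        build_wf_pairs(0.85, 2.4, 3.2, 1.6),
        [wf_header[0], wf_header[1], wf_header[2].format(R=3.2, K=1.6)],
    )
    write_pair_csv(
        "mpipi_recharged_pairs_synthetic.csv",
        build_wf_pairs(0.85, 2.4, 3.4, 1.4),
        [wf_header[0], wf_header[1], wf_header[2].format(R=3.4, K=1.4)],
    )

    yk = build_yukawa()
    lines = [
        "# SYNTHETIC STAND-IN Yukawa amplitude table for Mpipi-Recharged (kJ nm/mol):",
        "# screened-Coulomb scale at eps_r(298 K), x0.9 like-sign / x0.75 unlike-sign,",
        "# hence symmetric in i<->j but not reducible to a product of charges.",
        "i,j,A_kj_nm",
    ]
    lines += [f"{i},{j},{A}" for i, j, A in yk]
    (OUT / "mpipi_recharged_yukawa_synthetic.csv").write_text("\n".join(lines) + "\n")

    cp = [
        "# SYNTHETIC STAND-IN cation-pi epsilon table for HPS-cation-pi (kJ/mol):",
        "# uniform 3.0 kJ/mol for R/K x F/W/Y, the order of magnitude the model",
        "# publication adopts; sigma from Lorentz-Berthelot mixing at evaluation time.",
        "i,j,eps_kj",
    ]
    for i in CATIONIC:
        for j in AROMATIC:
            cp.append(f"{i},{j},3.0")
    (OUT / "hps_cation_pi_pairs_synthetic.csv").write_text("\n".join(cp) + "\n")

    registry = {
        "models": {
            "HPS": {
                "residues": "hps_residues.csv",
                "hydrophobic": "ashbaugh_hatch",
                "electrostatic": "debye_huckel_fixed_kappa",
                "ah_epsilon_kcal": 0.2,
                "kappa_nm_inv": 1.0,
                "epsilon_r": 80.0,
                "elec_cutoff_nm": 3.5,
                "hyd_cutoff_sigma": 3.0,
                "bond_k_kj_A2": 9.6,
            },
            "HPS-cation-pi": {
                "residues": "hps_residues.csv",
                "hydrophobic": "ashbaugh_hatch",
                "electrostatic": "debye_huckel_fixed_kappa",
                "ah_epsilon_kcal": 0.2,
                "kappa_nm_inv": 1.0,
                "epsilon_r": 80.0,
                "elec_cutoff_nm": 3.5,
                "hyd_cutoff_sigma": 3.0,
                "bond_k_kj_A2": 2.4,
                "cation_pi": "hps_cation_pi_pairs_synthetic.csv",
            },
            "HPS-Urry": {
                "residues": "hps_urry_residues.csv",
                "hydrophobic": "ashbaugh_hatch",
                "electrostatic": "debye_huckel_fixed_kappa",
                "ah_epsilon_kcal": 0.2,
                "kappa_nm_inv": 1.0,
                "epsilon_r": 80.0,
                "elec_cutoff_nm": 2.0,
                "hyd_cutoff_sigma": 3.0,
                "bond_k_kj_A2": 4.8,
            },
            "CALVADOS2": {
                "residues": "calvados2_residues.csv",
                "hydrophobic": "ashbaugh_hatch",
                "electrostatic": "debye_huckel_salt_T",
                "ah_epsilon_kcal": 0.2,
                "salt_mM": 150.0,
                "elec_cutoff_nm": 4.0,
                "hyd_cutoff_sigma": 3.0,
                "bond_k_kj_A2": 9.6,
            },
            "Mpipi": {
                "residues": "mpipi_residues_synthetic.csv",
                "hydrophobic": "wang_frenkel",
                "pairs": "mpipi_pairs_synthetic.csv",
                "electrostatic": "debye_huckel_fixed_kappa",
                "kappa_nm_inv": 1.26,
                "epsilon_r": 80.0,
                "elec_cutoff_nm": 3.5,
                "hyd_cutoff_sigma": 3.0,
                "bond_k_kj_A2": 9.6,
            },
            "Mpipi-Recharged": {
                "residues": "mpipi_recharged_residues_synthetic.csv",
                "hydrophobic": "wang_frenkel",
                "pairs": "mpipi_recharged_pairs_synthetic.csv",
                "electrostatic": "yukawa",
                "yukawa": "mpipi_recharged_yukawa_synthetic.csv",
                "salt_mM": 150.0,
                "elec_cutoff_nm": 3.5,
                "hyd_cutoff_sigma": 3.0,
                "bond_k_kj_A2": 9.6,
            },
        }
    }
    (OUT / "registry.yaml").write_text(yaml.safe_dump(registry, sort_keys=False))
    print("wrote parameter tables to", OUT)


if __name__ == "__main__":
    main()
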