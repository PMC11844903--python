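models:
  HPS:
    residues: hps_residues.csv
    hydrophobic: ashbaugh_hatch
    electrostatic: debye_huckel_fixed_kappa
    ah_epsilon_kcal: 0.2
    kappa_nm_inv: 1.0
    epsilon_r: 80.0
    elec_cutoff_nm: 3.5
    hyd_cutoff_sigma: 3.0
    bond_k_kj_A2: 9.6
  HPS-cation-pi:
    residues: hps_residues.csv
    hydrophobic: ashbaugh_hatch
    electrostatic: debye_huckel_fixed_kappa
    ah_epsilon_kcal: 0.2
    kappa_nm_inv: 1.0
    epsilon_r: 80.0
    elec_cutoff_nm: 3.5
    hyd_cutoff_sigma: 3.0
    bond_k_kj_A2: 2.4
    cation_pi: hps_cation_pi_pairs_synthetic.csv
  HPS-Urry:
    residues: hps_urry_residues.csv
    hydrophobic: ashbaugh_hatch
    electrostatic: debye_huckel_fixed_kappa
    ah_epsilon_kcal: 0.2
    kappa_nm_inv: 1.0
    epsilon_r: 80.0
    elec_cutoff_nm: 2.0
    hyd_cutoff_sigma: 3.0
    bond_k_kj_A2: 4.8
  CALVADOS2:
    residues: calvados2_residues.csv
    hydrophobic: ashbaugh_hatch
    electrostatic: debye_huckel_salt_T
    ah_epsilon_kcal: 0.2
    salt_mM: 150.0
    elec_cutoff_nm: 4.0
    hyd_cutoff_sigma: 3.0
    bond_k_kj_A2: 9.6
  Mpipi:
    residues: mpipi_residues_synthetic.csv
    hydrophobic: wang_frenkel
    pairs: mpipi_pairs_synthetic.csv
    electrostatic: debye_huckel_fixed_kappa
    kappa_nm_inv: 1.26
    epsilon_r: 80.0
    elec_cutoff_nm: 3.5
    hyd_cutoff_sigma: 3.0
    bond_k_kj_A2: 9.6
  Mpipi-Recharged:
    residues: mpipi_recharged_residues_synthetic.csv
    hydrophobic: wang_frenkel
    pairs: mpipi_recharged_pairs_synthetic.csv
    electrostatic: yukawa
    yukawa: mpipi_recharged_yukawa_synthetic.csv
    salt_mM: 150.0
    elec_cutoff_nm: 3.5
    hyd_cutoff_sigma: 3.0
    bond_k_kj_A2: 9.6
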