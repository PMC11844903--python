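"""Force-field oracles: scalar potentials, mixing rules, kernel agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgllps import forcefield as ff
from conftest import brute_force_energy


# ---------------------------------------------------------------------------
# electrostatics: dielectric law, Debye length
# ---------------------------------------------------------------------------


def test_dielectric_law_at_room_temperature():
    # hand evaluation of the quartic empirical law at 298.15 K
    T = 298.15
    expected = 5321.0 / T + 233.76 - 0.9297 * T + 1.417e-3 * T**2 - 8.292e-7 * T**3
    assert ff.dielectric_of_temperature(T) == pytest.approx(expected, rel=1e-14)
    assert 78.0 < expected < 79.0


def test_dielectric_strictly_decreasing_in_window():
    Ts = np.linspace(231.0, 449.0, 200)
    vals = [ff.dielectric_of_temperature(t) for t in Ts]
    assert np.all(np.diff(vals) < 0)


@pytest.mark.parametrize("T", [200.0, 230.0, 450.0, 500.0])
def test_dielectric_outside_window_rejected(T):
    with pytest.raises(ff.ForceFieldError):
        ff.dielectric_of_temperature(T)


def test_debye_kappa_physiological():
    # 150 mM monovalent salt, eps_r = 80, 298 K -> ~1.26 nm^-1 (0.79 nm length)
    kappa = ff.debye_kappa(150.0, 298.0, 80.0)
    assert kappa == pytest.approx(1.26, abs=0.01)


def test_debye_kappa_scaling_with_salt():
    # kappa ~ sqrt(c_s)
    k1 = ff.debye_kappa(100.0, 298.0, 80.0)
    k4 = ff.debye_kappa(400.0, 298.0, 80.0)
    assert k4 == pytest.approx(2.0 * k1, rel=1e-12)


def test_debye_kappa_zero_salt_and_negative():
    assert ff.debye_kappa(0.0, 298.0, 80.0) == 0.0
    with pytest.raises(ff.ForceFieldError):
        ff.debye_kappa(-1.0, 298.0, 80.0)


def test_debye_huckel_reduces_to_coulomb_at_zero_kappa():
    from cgllps.constants import COULOMB_KJ_NM

    r, eps_r = 0.8, 80.0
    expected = COULOMB_KJ_NM / eps_r / r
    assert ff.debye_huckel_energy(r, 1.0, 1.0, eps_r, 0.0) == pytest.approx(
        expected, rel=1e-14
    )


def test_debye_huckel_sign_and_screening():
    attract = ff.debye_huckel_energy(0.5, 1.0, -1.0, 80.0, 1.0)
    repel = ff.debye_huckel_energy(0.5, 1.0, 1.0, 80.0, 1.0)
    assert attract < 0 < repel
    assert abs(ff.debye_huckel_energy(2.0, 1.0, 1.0, 80.0, 2.0)) < abs(
        ff.debye_huckel_energy(2.0, 1.0, 1.0, 80.0, 0.5)
    )


def test_yukawa_matches_debye_huckel_with_equivalent_amplitude():
    from cgllps.constants import COULOMB_KJ_NM

    A = COULOMB_KJ_NM * (1.0 * -1.0) / 80.0
    for r in (0.4, 0.9, 1.7):
        assert ff.yukawa_energy(r, A, 1.3) == pytest.approx(
            ff.debye_huckel_energy(r, 1.0, -1.0, 80.0, 1.3), rel=1e-14
        )


# ---------------------------------------------------------------------------
# bonds
# ---------------------------------------------------------------------------


def test_bond_energy_hand_value():
    # k (r - r0)^2 with no 1/2 factor: k = 9.6, r = 4.81, r0 = 3.81 -> 9.6
    assert ff.bond_energy(4.81, 9.6, 3.81) == pytest.approx(9.6, rel=1e-12)
    assert ff.bond_energy(3.81) == 0.0


def test_bond_energy_symmetric_about_rest_length():
    assert ff.bond_energy(3.31) == pytest.approx(ff.bond_energy(4.31), rel=1e-12)


# ---------------------------------------------------------------------------
# Ashbaugh-Hatch
# ---------------------------------------------------------------------------


def test_ashbaugh_hatch_reduces_to_lj_at_lambda_one():
    eps, sigma = 0.8368, 0.55
    for r in (0.5, 0.6172, 0.9, 1.4):
        sr6 = (sigma / r) ** 6
        lj = 4 * eps * (sr6**2 - sr6)
        assert ff.ashbaugh_hatch_energy(r, eps, sigma, 1.0) == pytest.approx(
            lj, rel=1e-12, abs=1e-15
        )


def test_ashbaugh_hatch_purely_repulsive_at_lambda_zero():
    eps, sigma = 0.8368, 0.55
    rmin = 2 ** (1 / 6) * sigma
    assert ff.ashbaugh_hatch_energy(rmin * 0.99, eps, sigma, 0.0) > 0
    assert ff.ashbaugh_hatch_energy(rmin * 1.01, eps, sigma, 0.0) == 0.0


def test_ashbaugh_hatch_minimum_value():
    eps, sigma, lam = 0.8368, 0.55, 0.7
    rmin = 2 ** (1 / 6) * sigma
    assert ff.ashbaugh_hatch_energy(rmin, eps, sigma, lam) == pytest.approx(
        -lam * eps, rel=1e-12
    )


@settings(max_examples=200, deadline=None)
@given(
    eps=st.floats(0.01, 5.0),
    sigma=st.floats(0.3, 0.8),
    lam=st.floats(0.0, 1.0),
)
def test_ashbaugh_hatch_continuous_at_split(eps, sigma, lam):
    rmin = 2 ** (1 / 6) * sigma
    h = 1e-9 * sigma
    below = ff.ashbaugh_hatch_energy(rmin - h, eps, sigma, lam)
    above = ff.ashbaugh_hatch_energy(rmin + h, eps, sigma, lam)
    assert abs(below - above) < 1e-6 * eps + 1e-12


# ---------------------------------------------------------------------------
# Wang-Frenkel
# ---------------------------------------------------------------------------


def test_wang_frenkel_zeros_at_sigma_and_cutoff():
    eps, sigma, nu = 1.3, 0.5, 1.0
    assert ff.wang_frenkel_energy(sigma, eps, sigma, nu) == 0.0
    assert ff.wang_frenkel_energy(3.0 * sigma, eps, sigma, nu) == 0.0
    assert ff.wang_frenkel_energy(3.1 * sigma, eps, sigma, nu) == 0.0


@pytest.mark.parametrize("nu", [0.5, 1.0, 2.0, 3.0])
def test_wang_frenkel_depth_is_minus_eps(nu):
    eps, sigma = 0.77, 0.61
    rmin = ff.wang_frenkel_rmin(sigma, nu)
    assert ff.wang_frenkel_energy(rmin, eps, sigma, nu) == pytest.approx(
        -eps, rel=1e-12
    )
    # rmin is a genuine minimum
    for h in (1e-4, -1e-4):
        assert ff.wang_frenkel_energy(rmin * (1 + h), eps, sigma, nu) > -eps


def test_wang_frenkel_alpha_hand_value():
    # mu = 1, rc = 3 sigma, nu = 1: alpha = 2 * 9 * (3/16)^3 = 18 * 27/4096
    assert ff.wang_frenkel_alpha(1.0, 1.0, 3.0) == pytest.approx(
        2.0 * 9.0 * (3.0 / 16.0) ** 3, rel=1e-14
    )


def test_wang_frenkel_negative_between_rmin_and_cutoff():
    eps, sigma, nu = 1.0, 0.5, 1.0
    for r in np.linspace(1.01 * sigma, 2.99 * sigma, 20):
        assert ff.wang_frenkel_energy(float(r), eps, sigma, nu) < 0


# ---------------------------------------------------------------------------
# cation-pi
# ---------------------------------------------------------------------------


def test_cation_pi_only_for_valid_pairs():
    assert ff.cation_pi_energy(0.6, 3.0, 0.55, ("R", "F")) < 0
    assert ff.cation_pi_energy(0.6, 3.0, 0.55, ("Y", "K")) < 0
    with pytest.raises(ff.ForceFieldError):
        ff.cation_pi_energy(0.6, 3.0, 0.55, ("A", "F"))
    with pytest.raises(ff.ForceFieldError):
        ff.cation_pi_energy(0.6, 3.0, 0.55, ("R", "K"))


# ---------------------------------------------------------------------------
# model registry and mixing rules
# ---------------------------------------------------------------------------


def test_all_six_models_load_and_validate(all_models):
    assert set(all_models) == set(ff.MODEL_NAMES)
    for model in all_models.values():
        model.validate(ff.CANONICAL_RESIDUES)


def test_model_name_normalisation():
    assert ff.normalize_model_name("hps-urry") == "HPS-Urry"
    assert ff.normalize_model_name("MPIPI") == "Mpipi"
    with pytest.raises(ff.ForceFieldError):
        ff.normalize_model_name("no-such-model")


def test_lorentz_berthelot_sigma_and_lambda_mixing(all_models):
    model = all_models["HPS"]
    pc = model.pair_coefficients("A", "W")
    a, w = model.residues["A"], model.residues["W"]
    assert pc.sigma == pytest.approx(0.5 * (a.sigma + w.sigma), rel=1e-14)
    assert pc.lam == pytest.approx(0.5 * (a.hydropathy + w.hydropathy), rel=1e-14)


def test_pair_coefficients_symmetric(all_models):
    for model in all_models.values():
        for i, j in [("A", "W"), ("R", "Y"), ("K", "D"), ("F", "F")]:
            assert model.pair_coefficients(i, j) == model.pair_coefficients(j, i)


def test_hydropathy_orderings(all_models):
    lam = lambda m, c: m.residues[c].hydropathy  # noqa: E731
    hps = all_models["HPS"]
    assert lam(hps, "F") > lam(hps, "W") > lam(hps, "Y")
    urry = all_models["HPS-Urry"]
    assert lam(urry, "W") > lam(urry, "Y") > lam(urry, "F")
    calv = all_models["CALVADOS2"]
    assert lam(calv, "W") > lam(calv, "Y") > lam(calv, "F")


def test_model_specific_constants(all_models):
    assert all_models["HPS"].kappa(298.0) == pytest.approx(1.0)
    assert all_models["Mpipi"].kappa(298.0) == pytest.approx(1.26)
    assert all_models["HPS-Urry"].elec_cutoff == pytest.approx(2.0)
    assert all_models["CALVADOS2"].elec_cutoff == pytest.approx(4.0)
    assert all_models["HPS"].bond_k == pytest.approx(9.6)
    assert all_models["HPS-cation-pi"].bond_k == pytest.approx(2.4)
    assert all_models["HPS-Urry"].bond_k == pytest.approx(4.8)
    # temperature-dependent dielectric models
    assert all_models["CALVADOS2"].epsilon_r(298.0) != all_models["CALVADOS2"].epsilon_r(320.0)


def test_cation_pi_table_only_in_cation_pi_model(all_models):
    assert all_models["HPS-cation-pi"].cation_pi_eps
    assert not all_models["HPS"].cation_pi_eps


# ---------------------------------------------------------------------------
# kernel vs brute force, forces vs central differences
# ---------------------------------------------------------------------------


def test_kernel_energy_matches_brute_force(all_models, random_configuration):
    cfg = random_configuration()
    for model in all_models.values():
        e_kernel, _ = ff.total_energy_forces(model, cfg)
        e_ref = brute_force_energy(model, cfg)
        assert e_kernel == pytest.approx(e_ref, rel=1e-10)


def test_forces_match_central_differences(all_models, random_configuration):
    cfg = random_configuration(n=12, n_chains=2, seed=11)
    h = 1e-6
    for name in ("HPS", "HPS-cation-pi", "Mpipi", "Mpipi-Recharged"):
        model = all_models[name]
        _, forces = ff.total_energy_forces(model, cfg)
        rng = np.random.default_rng(0)
        for bead in rng.choice(cfg.n_beads, 4, replace=False):
            for axis in range(3):
                cp = cfg.copy()
                cp.positions[bead, axis] += h
                ep, _ = ff.total_energy_forces(model, cp)
                cm = cfg.copy()
                cm.positions[bead, axis] -= h
                em, _ = ff.total_energy_forces(model, cm)
                numeric = -(ep - em) / (2 * h)
                assert forces[bead, axis] == pytest.approx(
                    numeric, rel=5e-5, abs=5e-4
                )


def test_forces_sum_to_zero(all_models, random_configuration):
    cfg = random_configuration(seed=8)
    for model in all_models.values():
        _, forces = ff.total_energy_forces(model, cfg)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9


def test_energy_invariant_under_translation(all_models, random_configuration):
    cfg = random_configuration(seed=5)
    model = all_models["CALVADOS2"]
    e0, _ = ff.total_energy_forces(model, cfg)
    cp = cfg.copy()
    cp.positions += np.array([1.37, -2.11, 0.59])
    cp.wrap()
    e1, _ = ff.total_energy_forces(model, cp)
    assert e1 == pytest.approx(e0, rel=1e-10)


# ---------------------------------------------------------------------------
# interaction-strength matrices
# ---------------------------------------------------------------------------


def test_interaction_matrix_normalised_and_symmetric(all_models):
    for model in all_models.values():
        m = ff.interaction_strength_matrix(model)
        arr = m.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.abs(arr).max() == pytest.approx(1.0)


def test_interaction_matrix_aromatics_dominate(all_models):
    # in every model the strongest pairs involve aromatics and/or arginine
    for name, model in all_models.items():
        m = ff.interaction_strength_matrix(model)
        strongest = m.stack().idxmax()
        assert set(strongest) & (set("FWY") | {"R", "K"}), (name, strongest)
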