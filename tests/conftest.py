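"""Shared fixtures and an independent brute-force energy reference.

The brute-force implementation below deliberately avoids the package's
kernels and neighbour lists: it loops over every pair with explicit
minimum-image arithmetic and calls only the scalar potential functions, so
it serves as an oracle for the vectorised/numba code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from cgllps import forcefield as ff
from cgllps.system import Configuration


@pytest.fixture(scope="session")
def all_models():
    return {name: ff.load_model(name) for name in ff.MODEL_NAMES}


@pytest.fixture(scope="session")
def toy():
    from cgllps.synthetic import toy_model

    return toy_model()


@pytest.fixture()
def random_configuration():
    def make(n=24, n_chains=4, box_side=4.0, seed=3):
        rng = np.random.default_rng(seed)
        box = np.array([box_side] * 3)
        pos = rng.uniform(0, box_side, size=(n, 3))
        res = rng.choice(list(ff.CANONICAL_RESIDUES), n)
        if n % n_chains:
            raise ValueError("n must divide evenly into chains")
        chains = np.repeat(np.arange(n_chains), n // n_chains)
        return Configuration(pos, box, chains, res)

    return make


def brute_force_energy(model, cfg, T=298.0):
    """O(N^2) reference energy using only scalar potential functions."""
    box = cfg.box
    bonds = {tuple(b) for b in map(tuple, cfg.bonds())}
    kappa = model.kappa(T)
    eps_r = model.epsilon_r(T)
    e = 0.0
    for i in range(cfg.n_beads):
        for j in range(i + 1, cfg.n_beads):
            d = cfg.positions[i] - cfg.positions[j]
            d -= box * np.round(d / box)
            r = float(np.linalg.norm(d))
            if (i, j) in bonds:
                # bond_energy takes Angstrom units
                e += ff.bond_energy(r * 10.0, model.bond_k, model.bond_r0)
                continue
            ci, cj = str(cfg.residues[i]), str(cfg.residues[j])
            pc = model.pair_coefficients(ci, cj)
            rc_hyd = model.hyd_cutoff_sigma * pc.sigma
            if model.hydrophobic_scheme == "ashbaugh_hatch":
                if r < rc_hyd:
                    e += ff.ashbaugh_hatch_energy(r, pc.eps, pc.sigma, pc.lam)
                    if pc.cation_pi_eps > 0:
                        e += ff.cation_pi_energy(r, pc.cation_pi_eps, pc.sigma, (ci, cj))
            else:
                e += ff.wang_frenkel_energy(r, pc.eps, pc.sigma, pc.nu, model.mu, rc_hyd)
            if r < model.elec_cutoff:
                if model.electrostatic_scheme == "yukawa":
                    e += ff.yukawa_energy(r, pc.yukawa_A, kappa)
                else:
                    qq = model.residues[ci].charge * model.residues[cj].charge
                    e += ff.debye_huckel_energy(r, 1.0, qq, eps_r, kappa)
    return e
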