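# cgllps

Residue-resolution coarse-grained models and an end-to-end analysis pipeline
for liquid–liquid phase separation of disordered proteins.

The package implements six published one-bead-per-residue force fields
(HPS, HPS-cation-π, HPS-Urry, CALVADOS2, Mpipi, Mpipi-Recharged), Langevin
dynamics for direct-coexistence slab and bulk systems, and the analysis
stack used to benchmark such models against experiment: slab density
profiles and coexistence densities, critical-point fits, intermolecular
contact maps, Green–Kubo viscosities with Maxwell-mode long-time extension,
and log-scale deviation metrics.

See `docs/methods.md` for equations, units, estimator details, and the
split between the desk-scale tier (validated here) and the optional
cluster-scale tier.

## Quick start

```python
from cgllps import load_model, interaction_strength_matrix, load_a1_lcd_variants

model = load_model("CALVADOS2")
print(model.kappa(298.0))                      # Debye screening, nm^-1
print(interaction_strength_matrix(model))      # normalised pair strengths

variants = load_a1_lcd_variants()              # WT+NLS, allF, allY, allW, ...
```

Run a small simulation and analyse it:

```python
from cgllps import simulator, phase
from cgllps.sequences import ProteinSequence
from cgllps.synthetic import toy_model

model = toy_model()                            # fast synthetic test model
seq = ProteinSequence("toy", "WGWGWGWGWG")
cfg = simulator.build_slab_configuration(model, seq, n_chains=10,
                                         cross_section=16.0, length=24.0,
                                         seed=1, occupied_fraction=0.25)
settings = simulator.SimulationSettings(temperature=150.0, n_steps=50000,
                                        traj_stride=5000)
traj, stress, energies = simulator.run_langevin(cfg, model, settings)
profile = phase.density_profile(traj, model, n_bins=40)
print(phase.coexistence_densities(profile))
```

Command line (installed as `cgllps`):

```bash
cgllps ff-matrix Mpipi                          # pair-strength matrix
cgllps simulate --model HPS --sequence WT+NLS --n-chains 10 --steps 10000
cgllps phase run_traj.csv --model HPS           # densities from a trajectory
cgllps viscosity run_stress.csv                 # Green-Kubo viscosity
cgllps critical-fit coexistence.csv             # Tc / rho_c fit
cgllps benchmark exp.csv sim.csv --reference WT # log-scale deviations
cgllps synth stress --seed 1 --out stress.csv   # labelled synthetic fixtures
```

## Data provenance

Residue parameter tables ship under `src/cgllps/data/models/`. The
Wang–Frenkel pair tables, Yukawa amplitudes, and the A1-LCD variant FASTA
are **synthetic stand-ins** constructed by documented rules (headers in the
files, builders in `scripts/`); they preserve the qualitative structure of
the published parameters (aromatic ordering, charge products, sticker
compositions) but are not the published numbers.

## Tests and acceptance

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities (Debye length,
force-field oracle error, critical-fit and viscosity recovery, toy-slab
phase separation and equipartition) and writes them as JSON.

`scripts/cluster_tier.py` documents the optional large-scale benchmark
tier; it is a dry run unless `--confirm` is given.
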