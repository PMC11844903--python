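"""Optional cluster-scale benchmark tier (NOT run by tests or CI).

The desk-scale package validates every algorithm on toy systems.  Producing
publication-grade phase diagrams and viscosities for the full 137-residue
A1-LCD variants requires direct-coexistence slabs of ~100 chains simulated
for microseconds at several temperatures per model - weeks of CPU time.
This script documents and orchestrates that tier; it refuses to start
without an explicit --confirm so nobody launches it by accident.

Workflow per (model, variant, temperature):
  1. build a 100-chain slab (17 x 17 x 120 nm) with a pre-formed dense region
  2. equilibrate 100 ns, then run >= 2 us of production Langevin dynamics
  3. reduce the trajectory to a density profile; fit coexistence densities
  4. fit the critical point over the temperature ladder (alpha = 3.06)
  5. for the dense phase: build a bulk box at the coexistence density,
     record the stress tensor every 100 fs, and estimate the viscosity by
     the hybrid Green-Kubo / Maxwell-mode route
  6. score saturation concentrations and viscosities against experimental
     tables with the log-scale deviation metrics

Example:
    python scripts/cluster_tier.py --model CALVADOS2 --variant WT+NLS \
        --temperatures 280 290 300 310 --chains 100 --confirm
"""

from __future__ import annotations

import argparse


def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=__doc__.split("\n")[0])
    p.add_argument("--model", default="CALVADOS2")
    p.add_argument("--variant", default="WT+NLS")
    p.add_argument("--temperatures", nargs="+", type=float, required=False,
                   default=[280.0, 290.0, 300.0, 310.0])
    p.add_argument("--chains", type=int, default=100)
    p.add_argument("--production-ns", type=float, default=2000.0)
    p.add_argument("--out-dir", default="cluster_results")
    p.add_argument("--confirm", action="store_true",
                   help="actually launch the (very long) simulations")
    return p


def main() -> None:
    args = build_parser().parse_args()
    if not args.confirm:
        print(__doc__)
        print("Dry run only. Re-run with --confirm on a machine with weeks of "
              "CPU budget to launch the simulations described above.")
        return

    # Imports are deferred so a dry run never touches the heavy stack.
    from cgllps import phase, simulator
    from cgllps.forcefield import load_model
    from cgllps.lammps_io import write_stress_csv, write_trajectory_csv
    from cgllps.sequences import load_a1_lcd_variants
    from pathlib import Path

    model = load_model(args.model)
    seq = load_a1_lcd_variants()[args.variant]
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    steps = int(args.production_ns * 1e5)  # 10 fs steps
    points = []
    for T in args.temperatures:
        cfg = simulator.build_slab_configuration(
            model, seq, args.chains, cross_section=17.0 * 17.0, length=120.0,
            seed=1, occupied_fraction=0.3,
        )
        settings = simulator.SimulationSettings(
            temperature=T, n_steps=steps, seed=2, traj_stride=100000,
            stress_stride=10, energy_stride=1000,
        )
        traj, stress, energies = simulator.run_langevin(cfg, model, settings)
        tag = f"{args.model}_{args.variant}_{T:.0f}K"
        write_trajectory_csv(out / f"{tag}_traj.csv", traj)
        if stress is not None:
            write_stress_csv(out / f"{tag}_stress.csv", stress)
        prof = phase.density_profile(traj, model, n_bins=200)
        fit = phase.coexistence_densities(prof)
        if not fit.single_phase:
            points.append(phase.CoexistencePoint(T, fit.rho_l, fit.rho_v))
            print(f"{tag}: rho_l={fit.rho_l:.4f} rho_v={fit.rho_v:.5f} g/cm^3")
        else:
            print(f"{tag}: single phase")
    if len(points) >= 3:
        cp = phase.fit_critical_point(points)
        print(f"critical point: Tc = {cp.Tc:.1f} +- {cp.Tc_err:.1f} K, "
              f"rho_c = {cp.rho_c:.4f} g/cm^3")


if __name__ == "__main__":
    main()
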