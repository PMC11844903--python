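# Methods

This document states the model equations, algorithms, units, and estimator
choices implemented by `cgllps`, and records where the desk-scale tier ends
and the optional cluster tier begins.

## Units

Internal units are nm (length), ps (time), kJ/mol (energy), K (temperature),
e (charge), and g/mol (mass). These are self-consistent: 1 kJ/mol per g/mol
equals 1 (nm/ps)². Converters live at the I/O boundaries only:

- bond constants are quoted in kJ/(mol·Å²) and rest lengths in Å, as in the
  source publications;
- Ashbaugh–Hatch ε is quoted in kcal/mol (× 4.184 to kJ/mol);
- pressure/stress: 1 kJ/(mol·nm³) = 16.6054 bar; viscosity: 1 bar·ps =
  10⁻⁴ mPa·s;
- mass density: beads per nm³ × g/mol × 1.66054 → g/cm³.

## Force fields

All six packaged models are one-bead-per-residue with the shared energy

```
E = E_bonds + E_electrostatic + E_hydrophobic (+ E_cation-pi)
```

**Bonds.** Harmonic, `E = k (r − r0)²` with no ½ factor; `r0 = 3.81 Å`.
`k = 9.6 kJ/(mol·Å²)` (HPS, CALVADOS2, Mpipi, Mpipi-Recharged),
`2.4` (HPS-cation-π), `4.8` (HPS-Urry).

**Hydrophobic, Ashbaugh–Hatch (HPS family, CALVADOS2).** A split
Lennard-Jones: below the LJ minimum `2^(1/6)σ` the full LJ shifted up by
`(1−λ)ε`; above it the LJ tail scaled by `λ`. `σ` and `λ` mix
arithmetically (Lorentz–Berthelot); `ε = 0.2 kcal/mol = 0.8368 kJ/mol`.
The two branches meet continuously at `−λε`. Cutoff `3σᵢⱼ`, plain
truncation.

**Hydrophobic, Wang–Frenkel (Mpipi family).** Pair-specific `(ε, σ, ν)`
with `μ = 1`, `r_c = 3σ`:

```
U = ε α (σ/r)^{2μ} − 1) ((r_c/r)^{2μ} − 1)^{2ν},
α = 2ν (r_c/σ)^{2μ} [ (1+2ν) / (2ν ((r_c/σ)^{2μ} − 1)) ]^{2ν+1}
```

`α` makes the well depth exactly `−ε`; the potential is zero at `σ` and at
`r_c`.

**Electrostatics.** Debye–Hückel `k_e q_i q_j e^{−κr} / (ε_r r)` for all
models except Mpipi-Recharged, which uses a pair-amplitude Yukawa
`A_ij e^{−κr}/r`. κ is either fixed (HPS family: 1.0 nm⁻¹; Mpipi:
1.26 nm⁻¹) or derived from the salt concentration and temperature
(CALVADOS2, Mpipi-Recharged) via `κ = sqrt(8π ℓ_B c_s)` with Bjerrum length
`ℓ_B = k_e/(ε_r k_B T)` and the empirical dielectric law

```
ε_r(T) = 5321/T + 233.76 − 0.9297 T + 1.417·10⁻³ T² − 8.292·10⁻⁷ T³
```

valid for 230–450 K. At 150 mM, ε_r = 80, 298 K this gives
κ ≈ 1.26 nm⁻¹. Electrostatic cutoffs: 3.5 nm default, 2.0 nm (HPS-Urry),
4.0 nm (CALVADOS2); plain truncation.

**Cation-π (HPS-cation-π only).** An extra 12-6 LJ attraction between
{R, K} × {F, W, Y} pairs.

**Parameter provenance.** Residue tables (charge, σ, mass, λ scales for
HPS / Urry / CALVADOS2) are packaged under `src/cgllps/data/models/`. The
Wang–Frenkel pair tables and Yukawa amplitude tables are *synthetic
stand-ins* constructed by documented rules (see the file headers and
`scripts/build_parameter_tables.py`); the published pair tables were not
available when the package was assembled. Files carry `synthetic` in their
provenance headers. The packaged A1-LCD variant FASTA is likewise a
synthetic reconstruction honouring the published aromatic compositions
(8Y + 12F wild type; 19 mutable sticker positions; variants allF 19F,
allY 20Y, allW 19W, YtoW 7W+12F, FtoW 12W+8Y, W− 13W with 6 glycine
spacers).

## Simulation

Langevin dynamics with BAOAB splitting; default time step 10 fs, thermostat
relaxation 5 ps. With the thermostat disabled the integrator reduces to
velocity Verlet. Neighbour lists use a periodic k-d tree with a 0.3 nm
skin, rebuilt when any bead has moved half the skin. Virial stress is
`(Σ m v⊗v + Σ f⊗r)/V` with minimum-image pair vectors.

Builders: direct-coexistence slabs insert chains as self-avoiding random
walks in an elongated box (optionally into a central z-window to pre-form
the dense slab); bulk boxes are compressed isotropically in ≤7 % stages
with short relaxations until the target density is met within 1 %.

Truncated (unshifted) potentials leak a small amount of energy at cutoff
crossings; NVE runs therefore show a bounded drift unrelated to the
integrator, which is verified separately on a cutoff-free harmonic dimer.

## Phase analysis

Per-frame density profiles along z are recentred on the dense slab with the
mass-weighted circular mean before averaging. Coexistence densities come
from a two-interface tanh fit; profiles whose 10–90 percentile contrast is
below 20 % of the mean are reported as single-phase rather than force-fit.

Critical points are fitted jointly from

```
(ρ_l − ρ_v)^3.06 = s1 (1 − T/T_c)
(ρ_l + ρ_v)/2    = ρ_c + s2 (T_c − T)
```

by nonlinear least squares with the exponent held at 3.06 (the exponent
sits on the density difference; this is the reciprocal-β convention of the
3D Ising class, β ≈ 0.327). The T_c uncertainty is the spread of refits on
the last two, three, and four temperatures.

## Contacts

A contact is an intermolecular bead pair within `1.2 σᵢⱼ`. Frequencies are
per-frame averages per residue-type pair. Ranked interaction strengths are

```
S_ij = f_ij · (E_hyd + E_elec at the mean contact distance) / (N_i N_j)
```

sign-flipped so attraction is positive and normalised to a maximum of 1.

## Rheology

The relaxation modulus is the multi-component Green–Kubo estimator

```
G(t) = V/(5 k_B T) [ ⟨σxy σxy⟩ + ⟨σxz σxz⟩ + ⟨σyz σyz⟩
                     + (1/6)(⟨Nxy Nxy⟩ + ⟨Nxz Nxz⟩ + ⟨Nyz Nyz⟩) ]
```

with `N_ab = σ_aa − σ_bb`, all autocorrelations averaged over every time
origin by FFT with unbiased lag normalisation. The viscosity is the hybrid

```
η = ∫₀^{t₀} G dt  (trapezoid)  +  Σᵢ Gᵢ τᵢ  (Maxwell modes for t > t₀)
```

`t₀` is the earliest lag after which the smoothed modulus is positive and
decays monotonically (5 % noise allowance) over one decade. Maxwell modes
are non-negative least squares on a log-equidistant τ grid, four modes per
decade by default. Validation uses Ornstein–Uhlenbeck stress series with
analytically known `G(t)`: off-diagonal components receive OU modes of
autocovariance `cᵢ e^{−t/τᵢ}` and diagonal components `2cᵢ e^{−t/τᵢ}`, so
the estimator recovers `Σ Gᵢ e^{−t/τᵢ}` exactly in expectation.

## Benchmark metrics

Saturation concentrations and viscosities are compared on log scales:

```
D_rel = (1/n) Σ |log₁₀ x_exp − log₁₀ x_sim| / |log₁₀ x_exp|
D_rms = sqrt( (1/n) Σ (log₁₀ x_exp − log₁₀ x_sim)² )
```

`D_rel` is undefined when `x_exp = 1`; such points are rejected explicitly.
Experimental values from different sources are first normalised per source
against a shared reference variant.

## Desk tier vs cluster tier

Everything exercised by the test suite runs on one CPU core in minutes:
toy-model slabs (tens of chains, ≤10-bead chains), synthetic coexistence
curves, and OU stress series. Publication-grade phase diagrams and
viscosities for the 137-residue variants need ~100-chain slabs simulated
for microseconds across temperature ladders — weeks of CPU per model. That
cluster tier is **documented and optional**: `scripts/cluster_tier.py`
describes and orchestrates the workflow but refuses to run without an
explicit `--confirm` flag, and nothing in the installed package or the test
suite imports or requires it.
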