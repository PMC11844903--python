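"""Physical constants and unit conversions.

Internal unit system: length nm, time ps, energy kJ/mol, temperature K,
charge e (elementary charges), mass g/mol.  In these units 1 kJ/mol of
kinetic energy per g/mol of mass corresponds to (nm/ps)^2 exactly, so the
equations of motion need no hidden conversion factors.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 values."""

    elementary_charge: float = 1.602176634e-19  # C
    vacuum_permittivity: float = 8.8541878128e-12  # F/m
    boltzmann: float = 1.380649e-23  # J/K
    avogadro: float = 6.02214076e23  # 1/mol


CODATA = PhysicalConstants()

#: Gas constant in kJ/(mol K)
KB = CODATA.boltzmann * CODATA.avogadro / 1000.0

#: Coulomb constant e^2 N_A / (4 pi eps0) expressed in kJ nm / (mol e^2)
COULOMB_KJ_NM = (
    CODATA.elementary_charge**2
    * CODATA.avogadro
    / (4.0 * 3.141592653589793 * CODATA.vacuum_permittivity)
    / 1000.0  # J -> kJ
    * 1e9  # 1/m -> 1/nm
)

#: kcal/mol -> kJ/mol
KCAL_TO_KJ = 4.184

#: number density of a 1 mM solution in nm^-3
MM_TO_PER_NM3 = 1e-3 * CODATA.avogadro * 1e-24

#: internal pressure unit kJ/(mol nm^3) expressed in bar
PRESSURE_KJ_NM3_TO_BAR = 1000.0 / CODATA.avogadro / 1e-27 / 1e5

#: bar ps -> mPa s  (1 bar ps = 1e5 Pa * 1e-12 s = 1e-7 Pa s = 1e-4 mPa s)
BAR_PS_TO_MPA_S = 1e-4

#: g/mol per nm^3 -> g/cm^3
MASS_DENSITY_TO_G_CM3 = 1.0 / (CODATA.avogadro * 1e-21)
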