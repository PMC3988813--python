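"""Physical constants and unit conversions.

Internal unit system: lengths in nm, energies in kJ/mol, charges in
elementary charges, temperatures in K, times in ps.  All conversions to
SI happen at module boundaries.
"""

from __future__ import annotations

# CODATA 2018 exact values
BOLTZMANN_J = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Boltzmann constant in the internal energy unit, kJ/(mol K)
KB_KJMOL = BOLTZMANN_J * AVOGADRO / 1000.0  # ~0.008314

#: molar mass of water, kg/mol
WATER_MOLAR_MASS = 0.018015

NM = 1e-9  # m per nm
ANGSTROM_TO_NM = 0.1


def kj_per_mol_to_joule(e: float) -> float:
    """Convert a per-molecule energy from kJ/mol to J."""
    return e * 1000.0 / AVOGADRO


def joule_to_kj_per_mol(e: float) -> float:
    return e * AVOGADRO / 1000.0


def kj_per_mol_to_j_per_kg(e: float) -> float:
    """Convert a per-molecule energy (kJ/mol) to a specific energy (J/kg)
    using the molar mass of water."""
    return e * 1000.0 / WATER_MOLAR_MASS
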