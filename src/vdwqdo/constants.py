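"""Physical constants and unit conversions.

All internal math is carried out in Hartree atomic units
(hbar = e = m_e = k_e = 1; lengths in bohr, energies in hartree).
Conversions are applied only at I/O boundaries.
"""

from __future__ import annotations

#: CODATA fine-structure constant (dimensionless).
FINE_STRUCTURE = 7.2973525693e-3

#: Coulomb constant k_e = 1/(4 pi eps0) in atomic units.
COULOMB_KE = 1.0

#: hbar in atomic units.
HBAR = 1.0

#: Energy conversions.
HARTREE_TO_MEV = 27211.386
HARTREE_TO_KELVIN = 315775.02
HARTREE_TO_KCALMOL = 627.5094741
#: Derived so that hartree->K == (hartree->meV) * (meV->K) identically.
MEV_TO_KELVIN = HARTREE_TO_KELVIN / HARTREE_TO_MEV

#: Length conversion.
BOHR_TO_ANGSTROM = 0.52917721

#: Proportionality coefficient of the vdW-radius scaling law
#: R_vdW = PHI * alpha1^(1/7) (all atomic units).  Evaluated at import
#: from the fine-structure constant, never hard-coded: the alpha1^(1/7)
#: law has PHI = alpha_fsc^(-4/21) ~= 2.5528 bohr.
VDW_RADIUS_PHI = FINE_STRUCTURE ** (-4.0 / 21.0)

ENERGY_UNITS = {
    "hartree": 1.0,
    "mev": HARTREE_TO_MEV,
    "kelvin": HARTREE_TO_KELVIN,
    "kcalmol": HARTREE_TO_KCALMOL,
}

LENGTH_UNITS = {
    "bohr": 1.0,
    "angstrom": BOHR_TO_ANGSTROM,
}


def energy_from_hartree(value, unit: str):
    """Convert an energy from hartree to ``unit`` (hartree/mev/kelvin/kcalmol)."""
    try:
        return value * ENERGY_UNITS[unit.lower()]
    except KeyError:
        raise ValueError(f"unknown energy unit {unit!r}; choose from {sorted(ENERGY_UNITS)}")


def length_from_bohr(value, unit: str):
    """Convert a length from bohr to ``unit`` (bohr/angstrom)."""
    try:
        return value * LENGTH_UNITS[unit.lower()]
    except KeyError:
        raise ValueError(f"unknown length unit {unit!r}; choose from {sorted(LENGTH_UNITS)}")
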