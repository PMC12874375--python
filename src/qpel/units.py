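"""Internal unit system and physical constants.

The package works throughout in the mutually consistent MD unit system

    mass    : amu
    length  : nm
    time    : ps
    energy  : kJ/mol   (1 kJ/mol = 1 amu nm^2/ps^2)

so that no unit conversions appear inside force or integration loops.
Temperatures are in K, inverse temperatures ``beta = 1/(KB*T)`` in mol/kJ.
Coordinates on disk (XYZ) are in Angstrom; frequencies are reported in cm^-1
where stated.  Constants are CODATA-2018 values expressed in these units.
"""

from __future__ import annotations

import math

#: Boltzmann constant / gas constant, kJ/(mol K)
KB = 8.31446261815324e-3

#: Reduced Planck constant, kJ/mol * ps  (= amu nm^2 / ps)
HBAR = 1.054571817e-34 * 6.02214076e23 * 1e-3 / 1e-12  # ~0.0635077993

#: Coulomb prefactor 1/(4 pi eps0), kJ/mol * nm / e^2
COULOMB = 138.935458

#: Speed of light, cm/ps (for wavenumber conversions)
C_CM_PS = 2.99792458e-2

#: Avogadro constant, 1/mol
NA = 6.02214076e23

#: 1 kcal in kJ (thermochemical calorie)
KCAL = 4.184

#: nm <-> Angstrom
NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0

# Atomic masses (amu), most abundant isotopes
MASS_H = 1.00782503207
MASS_D = 2.01410177812
MASS_T = 3.0160492779
MASS_O = 15.99491461957


def beta_from_T(T: float) -> float:
    """Inverse temperature beta = 1/(k_B T) in mol/kJ."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return 1.0 / (KB * T)


def omega_from_wavenumber(nu_cm: float) -> float:
    """Angular frequency (rad/ps) from a wavenumber in cm^-1."""
    return 2.0 * math.pi * C_CM_PS * nu_cm


def wavenumber_from_omega(omega: float) -> float:
    """Wavenumber (cm^-1) from an angular frequency in rad/ps."""
    return omega / (2.0 * math.pi * C_CM_PS)


def molar_volume_to_box_edge(v_cm3_mol: float, n_molecules: int) -> float:
    """Cubic box edge (nm) for ``n_molecules`` at molar volume v (cm^3/mol)."""
    if v_cm3_mol <= 0 or n_molecules < 1:
        raise ValueError("molar volume and molecule count must be positive")
    vol_nm3 = v_cm3_mol / NA * 1e21 * n_molecules
    return vol_nm3 ** (1.0 / 3.0)
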