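"""Physical constants and unit conversions used throughout the package.

Every derived constant here is computed from CODATA values supplied by
:mod:`scipy.constants` rather than hard-coded, so that the unit bookkeeping
is auditable.  The key quantity is ``K_F``, the factor converting an
integrated molar attenuation coefficient (epsilon in M^-1 cm^-1 integrated
over wavenumber in cm^-1) into a dimensionless oscillator strength,

    f = K_F * integral( epsilon(nu) d nu )

whose accepted literature value is 4.32e-9 mol L^-1 cm^2.
"""

from __future__ import annotations

import math

from scipy import constants as _c

# eV -> cm^-1: E[cm^-1] = E[eV] * EV_TO_WAVENUMBER
EV_TO_WAVENUMBER: float = _c.e / (_c.h * _c.c * 100.0)  # ~8065.544 cm^-1/eV

# hartree -> eV
HARTREE_TO_EV: float = _c.physical_constants["Hartree energy in eV"][0]

# Decadic molar attenuation coefficient (M^-1 cm^-1) -> absorption cross
# section (cm^2):  sigma = (1000 * ln10 / N_A) * epsilon.
# 1000 converts litres to cm^3 so that concentration becomes a number density.
EPSILON_TO_CROSS_SECTION: float = 1000.0 * math.log(10.0) / _c.N_A  # ~3.82e-21

# Oscillator strength per integrated band intensity.
# SI expression: f = [4 eps0 m_e c^2 ln10 / (N_A e^2)] * Int(eps dnu) with the
# integral in m^3 mol^-1 m^-2; the practical integral in (M^-1 cm^-1)(cm^-1)
# is larger by 1e-3 m^3/L * 1e4 m^-2/cm^-2 = 10, absorbed below.
K_F: float = (
    4.0 * _c.epsilon_0 * _c.m_e * _c.c**2 * math.log(10.0) * 10.0 / (_c.N_A * _c.e**2)
)  # ~4.319e-9 mol L^-1 cm^2


def ev_to_wavenumber(energy_ev: float) -> float:
    """Convert an energy in eV to a wavenumber in cm^-1."""
    return energy_ev * EV_TO_WAVENUMBER


def wavenumber_to_ev(wavenumber_cm: float) -> float:
    """Convert a wavenumber in cm^-1 to an energy in eV."""
    return wavenumber_cm / EV_TO_WAVENUMBER


def ev_to_hartree(energy_ev: float) -> float:
    return energy_ev / HARTREE_TO_EV


def wavenumber_to_nm(wavenumber_cm: float) -> float:
    """Convert a wavenumber in cm^-1 to a vacuum wavelength in nm."""
    if wavenumber_cm <= 0:
        raise ValueError("wavenumber must be positive")
    return 1.0e7 / wavenumber_cm
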