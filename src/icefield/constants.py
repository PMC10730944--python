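"""Physical constants used throughout the package.

Units are fixed package-wide: lengths in Å, potentials in V, projected
potentials in V·Å, spatial frequencies in cycles/Å, energies in keV.
"""

import scipy.constants as _sc

#: kappa = 2*pi*hbar^2 / (m_e * q_e), in V·Å².  This is the constant that
#: converts an electron scattering factor (Å) into an integrated projected
#: potential (V·Å·Å² per atom): the plane integral of a single atom's
#: projected potential equals kappa * fe(0).
KAPPA_V_A2: float = 2.0 * _sc.pi * _sc.hbar**2 / (_sc.m_e * _sc.e) * 1e20

#: Avogadro's number, mol⁻¹.
N_AVOGADRO: float = _sc.N_A

#: Molar mass of water, g·mol⁻¹.
MR_WATER: float = 18.015

#: Electron rest energy, keV.
ELECTRON_REST_ENERGY_KEV: float = _sc.m_e * _sc.c**2 / _sc.e / 1e3


def water_number_density(density_g_cm3: float) -> float:
    """Molecules per Å³ for a given mass density in g·cm⁻³."""
    return density_g_cm3 * N_AVOGADRO / (MR_WATER * 1e24)
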