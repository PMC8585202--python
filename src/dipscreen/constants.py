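"""Physical constants and unit conversions.

Single source of truth for CODATA values and for the unit chain used
throughout the engine: dipoles are handled in Debye, coordinates in
angstrom, masses in g/mol at the API surface, while all dynamics and
energy bookkeeping run in SI per-molecule units (m, kg, s, J).  Energies
are reported in kcal/mol on output.
"""

import math

#: Vacuum permittivity, C^2 J^-1 m^-1 (CODATA 2018).
EPS0 = 8.8541878128e-12

#: Boltzmann constant, J/K (exact, SI 2019).
KB = 1.380649e-23

#: Molar gas constant, J mol^-1 K^-1 (exact).
R_GAS = 8.31446261815324

#: Avogadro constant, mol^-1 (exact).
N_AVOGADRO = 6.02214076e23

#: One Debye in C m.
DEBYE = 3.33564e-30

#: One angstrom in m.
ANGSTROM = 1e-10

#: Thermochemical kilocalorie in J.
KCAL = 4184.0

#: Dipole-interaction prefactor: energy in J for dipoles in Debye and
#: separation in m is ``DIPOLE_PREFACTOR * (mu_a . mu_b) / (eps_r * r**3)``.
DIPOLE_PREFACTOR = DEBYE * DEBYE / (4.0 * math.pi * EPS0)


def mass_kg_from_gmol(mass_gmol: float) -> float:
    """Convert a molar mass in g/mol to a single-molecule mass in kg."""
    return mass_gmol * 1e-3 / N_AVOGADRO


def kcalmol_from_joule(energy_j: float) -> float:
    """Convert a per-molecule energy in J to kcal/mol."""
    return energy_j * N_AVOGADRO / KCAL


def joule_from_kcalmol(energy_kcalmol: float) -> float:
    """Convert kcal/mol to a per-molecule energy in J."""
    return energy_kcalmol * KCAL / N_AVOGADRO


def thermal_speed(mass_kg: float, temperature: float) -> float:
    """Speed at which the kinetic energy equals k_B T, m/s."""
    return math.sqrt(2.0 * KB * temperature / mass_kg)
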