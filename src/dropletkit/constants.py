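"""Physical constants and unit conversions used throughout the package.

Internal units: lengths in nm, times in ps, masses in amu, temperatures in K,
concentrations in molar (helpers return µM where stated), energies in kJ/mol,
surface tensions in mN/m.
"""

from __future__ import annotations

#: Boltzmann constant, J/K (CODATA 2018, exact).
K_BOLTZMANN = 1.380649e-23

#: Avogadro constant, 1/mol (exact SI).
N_AVOGADRO = 6.02214076e23

#: Molar gas constant, J/(mol K).
R_GAS = K_BOLTZMANN * N_AVOGADRO

#: Default simulation temperature, K (physiological).
DEFAULT_TEMPERATURE = 310.15

#: Default mass of a regular Martini coarse-grained bead, amu.
DEFAULT_BEAD_MASS = 72.0

#: Default bead-bead distance cutoff defining an inter-chain contact, nm.
CONTACT_CUTOFF_NM = 0.8

#: 1 nm^3 expressed in litres.
NM3_TO_LITRE = 1e-24

#: 1 J/m^2 expressed in mN/m.
JOULE_PER_M2_TO_MN_PER_M = 1000.0


def concentration_molar(n_molecules: float, volume_nm3: float) -> float:
    """Number of molecules in a volume (nm^3) as a molar concentration."""
    if volume_nm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_nm3}")
    return n_molecules / (N_AVOGADRO * volume_nm3 * NM3_TO_LITRE)


def concentration_micromolar(n_molecules: float, volume_nm3: float) -> float:
    """Number of molecules in a volume (nm^3) as a µM concentration."""
    return concentration_molar(n_molecules, volume_nm3) * 1e6
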