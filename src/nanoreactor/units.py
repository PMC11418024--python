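"""Unit system and physical constants.

The internal unit system is (amu, Å, fs).  The derived energy unit is
amu·Å²·fs⁻², which is numerically almost exactly 10^4 kJ/mol (the amu is
defined so that N_A · 1 amu = 1 g/mol to within 4e-10 relative).  All
constants below are derived from the 2019 SI exact definitions.
"""

from __future__ import annotations

# SI exact values (2019 redefinition) and CODATA amu
AMU_KG = 1.66053906660e-27      # kg
AVOGADRO = 6.02214076e23        # 1/mol (exact)
KB_J = 1.380649e-23             # J/K (exact)
PLANCK_J_S = 6.62607015e-34     # J·s (exact)
C_CM_PER_S = 2.99792458e10      # speed of light, cm/s (exact)

# 1 internal energy unit (amu·Å²·fs⁻²) in joules:
#   amu [kg] · (1e-10 m)² / (1e-15 s)²  =  amu_kg · 1e10 J
_EU_J = AMU_KG * 1e10

#: kJ/mol per internal energy unit  (≈ 9999.999997)
EU_TO_KJ_PER_MOL = _EU_J * AVOGADRO / 1000.0
KJ_PER_MOL_TO_EU = 1.0 / EU_TO_KJ_PER_MOL

#: Boltzmann constant in amu·Å²·fs⁻²·K⁻¹  (≈ 8.3144626e-7)
KB = KB_J / _EU_J

#: frequency conversion: internal angular frequency is fs⁻¹; ν[Hz] = ν[fs⁻¹]·1e15
FS_INV_TO_HZ = 1e15

#: wavenumber of a frequency given in fs⁻¹: ν/c with c in cm/s
FS_INV_TO_CM_INV = FS_INV_TO_HZ / C_CM_PER_S


def hz_to_kj_per_mol(nu_hz: float) -> float:
    """Photon energy h·ν of a frequency in Hz, as a molar energy in kJ/mol."""
    return PLANCK_J_S * nu_hz * AVOGADRO / 1000.0
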