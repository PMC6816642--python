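"""Centralized unit conversions.

Geometry (pores, particles, MD analysis cells) is specified in nm, as is
customary for molecular systems; transport quantities (diffusivities, times,
pressures) are SI. Every module converts at its boundary through the constants
below so that no factor of 1e-9 is ever written inline twice.
"""

NM_TO_M = 1e-9
NM2_TO_M2 = 1e-18
NM3_TO_M3 = 1e-27
PS_TO_S = 1e-12

#: 1 nm²/ps = 1e-6 m²/s — the internal unit of the MSD estimator.
NM2_PER_PS_TO_M2_PER_S = 1e-6

#: Avogadro constant [1/mol] (CODATA 2018 exact value).
AVOGADRO = 6.02214076e23


def number_density_to_molar(c_per_nm3: float) -> float:
    """Convert a number density [nm⁻³] to a molar concentration [mol/m³]."""
    return c_per_nm3 / NM3_TO_M3 / AVOGADRO
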