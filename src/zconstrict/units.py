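"""Internal unit system and physical constants.

Everything inside the package is expressed in nanometers (length),
piconewtons (force) and seconds (time).  Energies are therefore in
pN·nm (1 pN·nm = 1e-21 J).  Literature values quoted in SI are
converted once, at the configuration boundary, with the helpers here;
internal code never carries units.
"""

from __future__ import annotations

#: 1 joule in pN·nm
J_TO_PN_NM = 1e21

#: 1 atmosphere in pN/nm^2 (101325 Pa = 101325e-24 pN/nm^2 * 1e18 ... = 0.101325)
ATM_TO_PN_PER_NM2 = 0.101325

#: 1 N·s/m in pN·s/nm  (1 N = 1e12 pN, 1 m = 1e9 nm)
NS_PER_M_TO_PN_S_PER_NM = 1e3

#: Boltzmann constant in pN·nm/K
K_BOLTZMANN = 1.380649e-23 * J_TO_PN_NM


def joules(value: float) -> float:
    """Convert an energy (or torque-like constant) from J to pN·nm."""
    return value * J_TO_PN_NM


def atmospheres(value: float) -> float:
    """Convert a pressure from atm to pN/nm^2."""
    return value * ATM_TO_PN_PER_NM2
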