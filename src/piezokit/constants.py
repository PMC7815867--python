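"""Physical constants and unit conversions.

Internal unit system: length in Å (nm only where noted), time in ns,
voltage in mV, current in pA, conductance in pS, charge in elementary
charges. All conversions live here.
"""

#: elementary charge, coulomb
E_CHARGE_C = 1.602177e-19

#: Boltzmann constant, J/K
KB_J_PER_K = 1.380649e-23

#: default simulation temperature, K (body temperature)
T_DEFAULT_K = 310.15

#: kB*T at 310.15 K, zeptojoule (1 zJ = 1e-21 J)
KBT_ZJ = KB_J_PER_K * T_DEFAULT_K * 1e21  # = 4.2827 zJ

#: 1 mN/m * 1 nm^2 = 1e-3 N/m * 1e-18 m^2 = 1e-21 J = 1 zJ
TENSION_AREA_TO_ZJ = 1.0

#: 1 elementary charge per ns expressed in pA
E_PER_NS_TO_PA = E_CHARGE_C / 1e-9 * 1e12  # = 160.2177 pA


def kbt_zj(temperature_k: float = T_DEFAULT_K) -> float:
    """kB*T in zeptojoules at the given temperature."""
    return KB_J_PER_K * temperature_k * 1e21
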