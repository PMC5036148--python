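"""Physical constants and unit conversions.

Internal conventions: lengths in nm, times in ps, velocities in nm/ps,
particle masses in g/mol, mass densities in g/cm^3, temperatures in K.
Thermal quantities use the field's customary units: power densities in
GW/m^2, interfacial conductances in MW/m^2/K, conductivities in W/m/K.
"""

K_B = 1.380649e-23  # J/K
N_A = 6.02214076e23  # 1/mol
AMU_KG = 1.0 / N_A * 1e-3  # kg per (g/mol) unit of particle mass
AMU_G = 1.0 / N_A  # g per (g/mol)

M_CARBON = 12.011  # g/mol
M_WATER = 18.01528  # g/mol

NM = 1e-9  # m
PS = 1e-12  # s
NM_PER_PS = 1e3  # m/s per (nm/ps)

# 1 g/cm^3 expressed in g/nm^3
G_CM3_TO_G_NM3 = 1e-21

WATER_BULK_DENSITY = 0.997  # g/cm^3 at ambient conditions


def graphite_specific_heat() -> float:
    """Dulong-Petit specific heat of carbon, 3*N_A*k_B per mole, in J/g/K.

    Evaluates to ~2.08 J/g/K, the classical high-temperature limit used as
    the graphene sheet's specific heat c_g (quoted as 2.1 J/g/K).
    """
    return 3.0 * N_A * K_B / M_CARBON
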