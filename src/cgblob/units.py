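"""Unit system and physical constants.

Internal units: length A, time ps, mass amu, energy kcal/mol (converted to
amu A^2/ps^2 inside the integrator), temperature K.
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: 1 kcal/mol expressed in amu A^2 / ps^2
KCAL_PER_MOL = 418.4

#: rho [g/cm^3] * V [A^3] * DENSITY_FACTOR = total mass [amu]
DENSITY_FACTOR = 0.60221408

#: A^2/ps -> 1e-9 m^2/s
DIFFUSION_UNIT = 10.0

#: molar mass of C60, g/mol
C60_MOLAR_MASS = 60 * 12.011
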