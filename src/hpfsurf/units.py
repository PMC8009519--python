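"""Physical constants in the repository-wide unit system.

Lengths in nm, time in ps, mass in amu, energy in kJ/mol, temperature in K,
charge in units of the elementary charge.  This system is internally
consistent for dynamics: 1 amu * nm^2 / ps^2 = 1 kJ/mol exactly, so forces in
kJ/mol/nm divided by masses in amu give accelerations in nm/ps^2 with no
conversion factor.
"""

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083145

#: Avogadro constant, 1/mol.
NA = 6.02214076e23

#: Coulomb constant 1/(4 pi eps0), kJ/mol * nm / e^2.
KC = 138.935

#: nm^2/ps -> 1e-5 cm^2/s (the unit diffusion coefficients are reported in).
D_TO_1E5_CM2_S = 1.0e3
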