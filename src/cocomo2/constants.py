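"""Physical constants and unit conventions.

All quantities in the package use the MD unit system: lengths in nm,
energies in kJ/mol, time in ps, masses in amu, charges in elementary
units, temperatures in K.  In these units 1 amu * (nm/ps)^2 = 1 kJ/mol,
so kinetic energies need no conversion factor.
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.00831446261815324

#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

#: Coulomb constant e^2/(4 pi eps0) in kJ nm / mol
COULOMB = 138.935458

#: Relative permittivity of water used for the screened electrostatic term
WATER_EPS_R = 80.0
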