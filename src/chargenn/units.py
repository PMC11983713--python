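"""Unit system and physical constants.

The package works in the MD-native unit system: lengths in Å, energies in
kcal/mol, charges in elementary charge e, masses in amu, time in fs.
"""

#: Coulomb constant, kcal·Å/(mol·e²)
KE_COULOMB = 332.0637

#: Dipole conversion, Debye per e·Å
DEBYE_PER_E_ANGSTROM = 4.8032

#: Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041

#: Gas constant equals KB in molar units (kcal/mol/K)
R_GAS = KB

#: (kcal/mol/Å) / amu  ->  Å/fs²  (acceleration conversion)
FORCE_TO_ACC = 4.184e-4

#: amu·Å²/fs²  ->  kcal/mol  (kinetic-energy conversion)
KE_TO_KCAL = 1.0 / FORCE_TO_ACC

#: Atomic masses, amu
MASS = {"O": 15.9994, "H": 1.008}

#: Nuclear charges (used for the nuclear-charge-center dipole origin)
NUCLEAR_Z = {"O": 8.0, "H": 1.0}
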