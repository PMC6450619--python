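"""Internal unit system and physical constants.

Lengths are nm, energies kcal/mol, temperature K, charge e, time fs at the
API surface (ps internally in the integrator), masses amu.  LAMMPS ``units
real`` (Å, kcal/mol) conversion happens only in the table writers.
"""

# Boltzmann constant, kcal/(mol K)
KB_KCAL = 1.987204259e-3

# Boltzmann constant in amu nm^2 / ps^2 / K  (== kJ/mol/K numerically)
KB_KJ = 8.31446262e-3

# kcal/mol -> amu nm^2/ps^2 (== kJ/mol)
KCAL_TO_KJ = 4.184

# Coulomb prefactor q_i q_j / r with q in e, r in nm: kcal nm / (mol e^2).
# (The familiar 332.0637 kcal Å/(mol e^2) divided by 10.)
COULOMB_K = 33.20637133

# Molar masses, g/mol
WATER_MOLAR_MASS = 18.01528

NM_TO_ANGSTROM = 10.0
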