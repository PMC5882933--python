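"""Physical constants and unit conversions used throughout the package.

Geometry is carried in angstrom, charges in elementary charge units (e),
potentials in atomic units (hartree/e) and continuum-solvation energies in
kcal/mol.
"""

#: 1 angstrom expressed in bohr.
BOHR_PER_ANGSTROM = 1.8897259886

#: Coulomb constant in practical units: q1*q2/r [e^2/angstrom] -> kcal/mol.
COULOMB_KCAL = 332.0636

#: Standard link-hydrogen bond lengths by donor element (angstrom).
LINK_BOND_LENGTH = {"C": 1.090, "N": 1.010}

#: Hartree -> kcal/mol.
HARTREE_KCAL = 627.5094740631
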