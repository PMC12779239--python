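"""Physical constants and project-wide unit conventions.

Internal units are fixed across the package: length nm, time ps, energy
kJ/mol, charge in elementary charges, mass in amu, temperature K.
PDB coordinates (Angstrom) are converted at the I/O boundary.
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.008314462618

#: Coulomb conversion factor f = 1/(4 pi eps0), kJ mol^-1 nm e^-2
F_COULOMB = 138.935458

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 310.0

# SI values used only inside the Schlitter-entropy prefactor, where the
# argument (kB T e^2 / hbar^2) m sigma^2 must be dimensionless.
KB_SI = 1.380649e-23        # J/K
HBAR_SI = 1.054571817e-34   # J s
AVOGADRO = 6.02214076e23    # 1/mol
AMU_KG = 1.66053906892e-27  # kg
NM_M = 1.0e-9               # m

#: Angstrom per nm
ANGSTROM_PER_NM = 10.0

#: Standard atomic masses (amu) for elements that occur in protein systems.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "NA": 22.990, "CL": 35.45, "K": 39.098, "MN": 54.938,
    "X": 1.0,
}
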