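"""Physical constants and unit conventions.

Units used throughout the package: length Å, charge e, energy kJ/mol,
temperature K, pressure Torr, mass u.  1 kcal = 4.184 kJ exactly.
Internal trajectory units: velocity km/s (so that ½·m[u]·v² is in kJ/mol
directly), time 10⁻¹³ s.
"""

# gas constant, kJ/(mol K)
R_KJ = 8.31446261815324e-3

# Coulomb energy prefactor e²/(4πε₀) in kJ·Å/mol
COULOMB_KJ_A = 1389.35457644382

# exact thermochemical calorie
KCAL_TO_KJ = 4.184

# aqueous proton Gibbs free energy magnitude used in the thermodynamic
# cycle, kcal/mol (the cycle itself uses the negative of this value)
PROTON_GAQ_KCAL = 265.6

# Loschmidt number density at 273.15 K and 760 Torr, m⁻³
N0_STANDARD = 2.686781e25

ELEMENTARY_CHARGE = 1.602176634e-19      # C
ATOMIC_MASS_KG = 1.66053906660e-27       # kg
BOLTZMANN_SI = 1.380649e-23              # J/K

# masses (u) of the elements the pipeline accepts; "X" is the synthetic
# bead element emitted by the scenario generator
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
    "X": 40.0,
}
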