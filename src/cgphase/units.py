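"""Internal unit system and physical constants.

Everything inside the package is expressed in a single unit system:
length nm, time ps, mass amu, energy kJ/mol, charge e, temperature K.
Parameter files that quote kcal/mol are converted exactly once on load.
"""

#: Boltzmann constant, kJ/mol/K (molar gas constant).
KB = 0.00831446261815324

#: Coulomb prefactor e^2/(4 pi eps0) in kJ/mol * nm / e^2 (CODATA 2018).
COULOMB_KE = 138.93545764438198

#: Exact thermochemical calorie.
KCAL_TO_KJ = 4.184

#: 1 amu / nm^3 expressed in mg/mL.
AMU_PER_NM3_TO_MG_PER_ML = 1.66053906660

#: Vacuum permittivity * 4pi absorbed in COULOMB_KE; Debye length needs
#: eps0 kB/(2 NA e^2) in SI; we work via COULOMB_KE instead (see
#: forcefields.debye_length).
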