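"""Unit system and physical constants.

The package works in Å, ps, amu, kJ/mol, kelvin and elementary charges
throughout.  With these units the thermal energy at 300 K is
k_B*T = 2.494 kJ/mol and a unit point charge pair at 1 Å contributes
1389.35 kJ/mol in vacuum.
"""

#: Boltzmann constant, kJ/mol/K
KB = 0.0083144621

#: Coulomb prefactor e^2/(4 pi eps0), kJ/mol * Å / e^2 (vacuum)
COULOMB_K = 1389.35458
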