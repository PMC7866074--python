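"""Physical constants and unit conversions (CODATA 2018).

All public operations take and return the field's customary units
(T in K, Pc in bar, Vc in cm3/mol, sigma in Angstrom, eps/kB in K,
D12 in cm2/s, viscosity in cP); conversions live here and are applied
inside operations only.
"""

AVOGADRO = 6.02214076e23        # 1/mol
KB_J = 1.380649e-23             # J/K
KB_ERG = 1.380649e-16           # erg/K (CGS; erg = g cm2 s-2)
BAR_TO_PA = 1.0e5
ATM_IN_BAR = 1.01325
M_TO_ANGSTROM = 1.0e10
ANGSTROM_TO_CM = 1.0e-8
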