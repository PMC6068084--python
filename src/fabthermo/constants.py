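"""Physical constants used throughout the package (SI units).

Values are CODATA; ``R`` is kept at the four-digit value conventional in
binding thermodynamics so that reported energies match hand calculations
done with R = 8.314 J mol^-1 K^-1.
"""

#: Gas constant, J mol^-1 K^-1.
R = 8.314

#: Boltzmann constant, J K^-1.
KB = 1.380649e-23

#: Planck constant, J s.
H = 6.62607015e-34

#: Reference temperature for binding enthalpy/entropy, K (20 degC).
T_REF = 293.15
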