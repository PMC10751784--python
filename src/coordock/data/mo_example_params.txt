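# Example user override file: the two published molybdenum well depths.
# Format: TYPE_I TYPE_J EPS(kcal/mol) RMIN(Angstrom) EXPONENTS
# The Mo-HD 12-6 term dominates metal-assisted deprotonation of cysteine S-H;
# the Mo-SA well is correspondingly shallow.
Mo HD 5.62 1.00 12,6
Mo SA 0.17 2.30 12,10
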