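# Van der Waals radii (angstrom), Amber-type, keyed by element symbol.
# Atom-name overrides may be given as ELEMENT:ATOMNAME RADIUS and take
# precedence over the bare element entry.
H 1.20
C 1.70
N 1.625
O 1.48
S 1.80
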