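# van der Waals radii in Angstrom.
# Main-group values: Bondi (1964); transition metals: 2.05 A (common
# tabulated extension value used by cheminformatics periodic tables).
# columns: element  radius_A
H   1.20
C   1.70
N   1.55
O   1.52
F   1.47
S   1.80
Cl  1.75
Fe  2.05
Br  1.85
Ru  2.05
I   1.98
Pt  2.05
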