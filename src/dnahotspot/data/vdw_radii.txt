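# Van der Waals radii (Angstrom) by element, used for solvent-accessible
# surface area and contact geometry.  Values follow the heavy-atom radii
# commonly used by accessibility programs (Chothia 1976 / Naccess-compatible
# rounding).  Unknown elements fall back to 1.80 A with a warning.
# element  radius_A
C   1.70
N   1.55
O   1.52
S   1.80
P   1.80
H   1.20
D   1.20
SE  1.90
F   1.47
CL  1.75
BR  1.85
I   1.98
FE  1.40
ZN  1.39
MG  1.73
MN  1.40
NA  2.27
K   2.75
CA  2.31
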