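# Van der Waals radii by element, Angstrom (Bondi-style set).
# Hydrogens absent from crystal structures are simply not modelled;
# united-atom radii are NOT applied by default.
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
H	1.20
F	1.47
CL	1.75
BR	1.85
I	1.98
SE	1.90
ZN	1.39
MG	1.73
CA	2.31
NA	2.27
K	2.75
FE	1.63
MN	1.61
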