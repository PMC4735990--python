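# Isotropic surface area (I) scale: Collantes & Dunn (1995) J Med Chem 38:2705-2713.
# Side-chain isotropic surface area (ISA), Angstrom^2.
A	62.90
R	52.98
N	17.87
D	18.46
C	78.51
Q	19.53
E	30.19
G	19.93
H	87.38
I	149.77
L	154.35
K	102.78
M	132.22
F	189.42
P	122.35
S	19.75
T	59.44
W	179.16
Y	132.16
V	120.91
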