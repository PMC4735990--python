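# Hydropathy classes of protein heavy atoms, keyed by (residue, atom).
# Classes: donor (hydrophilic H-bond donor), acceptor (hydrophilic
# H-bond acceptor), donor_acceptor, hydrophobic, neutral.
# The row with residue "*" matches the backbone atoms of any residue.
# residue<TAB>atom<TAB>class
*	N	donor
*	CA	hydrophobic
*	C	neutral
*	O	acceptor
*	OXT	acceptor
ALA	CB	hydrophobic
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	neutral
ARG	NE	donor
ARG	CZ	neutral
ARG	NH1	donor
ARG	NH2	donor
ASN	CB	hydrophobic
ASN	CG	neutral
ASN	OD1	acceptor
ASN	ND2	donor
ASP	CB	hydrophobic
ASP	CG	neutral
ASP	OD1	acceptor
ASP	OD2	acceptor
CYS	CB	hydrophobic
CYS	SG	donor_acceptor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	neutral
GLN	OE1	acceptor
GLN	NE2	donor
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	neutral
GLU	OE1	acceptor
GLU	OE2	acceptor
HIS	CB	hydrophobic
HIS	CG	neutral
HIS	ND1	donor_acceptor
HIS	CD2	neutral
HIS	CE1	neutral
HIS	NE2	donor_acceptor
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	neutral
LYS	NZ	donor
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	neutral
MET	CE	hydrophobic
PHE	CB	hydrophobic
PHE	CG	hydrophobic
PHE	CD1	hydrophobic
PHE	CD2	hydrophobic
PHE	CE1	hydrophobic
PHE	CE2	hydrophobic
PHE	CZ	hydrophobic
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	neutral
SER	CB	neutral
SER	OG	donor_acceptor
THR	CB	neutral
THR	OG1	donor_acceptor
THR	CG2	hydrophobic
TRP	CB	hydrophobic
TRP	CG	hydrophobic
TRP	CD1	neutral
TRP	CD2	hydrophobic
TRP	NE1	donor
TRP	CE2	neutral
TRP	CE3	hydrophobic
TRP	CZ2	hydrophobic
TRP	CZ3	hydrophobic
TRP	CH2	hydrophobic
TYR	CB	hydrophobic
TYR	CG	hydrophobic
TYR	CD1	hydrophobic
TYR	CD2	hydrophobic
TYR	CE1	hydrophobic
TYR	CE2	hydrophobic
TYR	CZ	neutral
TYR	OH	donor_acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
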