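# Contact-legitimacy matrix between atom hydropathy classes.
# 1 = legitimate (chemically compatible contact), 0 = illegitimate.
# Hydrophilic-hydrophobic pairs MUST be 0 (validated at load time);
# like-polarity hydrophilic pairs (donor-donor, acceptor-acceptor) are
# incompatible; neutral atoms are compatible with everything.
	donor	acceptor	donor_acceptor	hydrophobic	neutral
donor	0	1	1	0	1
acceptor	1	0	1	0	1
donor_acceptor	1	1	1	0	1
hydrophobic	0	0	0	1	1
neutral	1	1	1	1	1
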