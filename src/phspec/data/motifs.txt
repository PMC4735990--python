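# Signature motif for 3-phosphate binding, spanning the beta1 strand /
# beta1-beta2 loop.  PROSITE-like syntax: literal residues, [sets],
# X wildcard, X(n,m) bounded gap.  One "name<TAB>pattern" per line.
# Default pattern after the basic-residue PtdIns(3,4,5)P3-binding
# signature of Isakoff et al. (1998) EMBO J 17:5374-5387; the exact
# published form is not asserted here and the pattern is overridable.
3p-signature	K-X-[SG]-X(6,11)-[KR]-X-R
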