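# Reference binding-specificity groups of representative PH domains.
# Group 1: specific, high-affinity Ins(1,3,4,5)P4 binders.
# Group 2: Ins(1,4,5)P3-preferring, 4-8-fold weaker affinity.
# Group 3: 3-phosphorylated-inositide binders incl. Ins(1,3,4)P3.
# Group 4: low affinity, little specificity.
domain	group
Btk	1
Grp1	1
Gap1m	1
Gap1IP4BP	1
Vav	1
cytohesin-1	1
Sos	1
ARNO	1
TIAM1-N	1
PLCd1	2
bArk	2
b-spectrin	2
DAGKd	2
RasGAp	2
OSBP	2
IRS-1	2
Plec-N	2
Dapp1	3
Akt	3
PDK1	3
Dynamin	4
TIAM1-C	4
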