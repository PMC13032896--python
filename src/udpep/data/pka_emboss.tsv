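# EMBOSS-style pKa set for Henderson-Hasselbalch net-charge and pI
# calculations (EMBOSS iep defaults).  sign +1 = basic group (protonated
# form positive), -1 = acidic group (deprotonated form negative).
# "nterm"/"cterm" are the free termini of the chain.
# version: 1
group	pka	sign
nterm	8.6	1
cterm	3.6	-1
C	8.5	-1
D	3.9	-1
E	4.1	-1
H	6.5	1
K	10.8	1
R	12.5	1
Y	10.1	-1
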