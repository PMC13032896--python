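# Wimley-White whole-residue water -> n-octanol transfer free energies
# (Wimley, Creamer & White 1996; White & Wimley 1999), kcal/mol.
# Stored hydrophobic-positive: value = -dG(water->octanol), so hydrophobic
# residues (W, F, I, L, ...) are positive and charged residues strongly
# negative.  Histidine is the neutral form; Asp/Glu are the charged forms.
# version: 1
residue	value
A	-0.50
C	0.02
D	-3.64
E	-3.63
F	1.71
G	-1.15
H	-0.11
I	1.12
K	-2.80
L	1.25
M	0.67
N	-0.85
P	-0.14
Q	-0.77
R	-1.81
S	-0.46
T	-0.25
V	0.46
W	2.09
Y	0.71
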