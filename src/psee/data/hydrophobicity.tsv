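# Eisenberg consensus hydrophobicity scale (normalized consensus of several
# experimental scales). class: H = hydrophobic, P = hydrophilic/polar.
aa	index	class
A	0.62	H
R	-2.53	P
N	-0.78	P
D	-0.90	P
C	0.29	P
Q	-0.85	P
E	-0.74	P
G	0.48	H
H	-0.40	P
I	1.38	H
L	1.06	H
K	-1.50	P
M	0.64	H
F	1.19	H
P	0.12	H
S	-0.18	P
T	-0.05	P
W	0.81	H
Y	0.26	H
V	1.08	H
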