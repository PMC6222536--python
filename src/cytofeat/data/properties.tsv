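# Physicochemical constants for type-I pseudo amino-acid composition:
# residue, hydrophilicity (Hopp-Woods), hydrophobicity (Chou scale),
# side-chain mass (Da). The canonical PseAAC-Builder constants.
A	-0.5	0.62	15.0
R	3.0	-2.53	101.0
N	0.2	-0.78	58.0
D	3.0	-0.90	59.0
C	-1.0	0.29	47.0
Q	0.2	-0.85	72.0
E	3.0	-0.74	73.0
G	0.0	0.48	1.0
H	-0.5	-0.40	82.0
I	-1.8	1.38	57.0
L	-1.8	1.06	57.0
K	3.0	-1.50	73.0
M	-1.3	0.64	75.0
F	-2.5	1.19	91.0
P	0.0	0.12	42.0
S	0.3	-0.18	31.0
T	-0.4	-0.05	45.0
W	-3.4	0.81	130.0
Y	-2.3	0.26	107.0
V	-1.5	1.08	43.0
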