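# Van der Waals volume of the residue (A^3), Bondi-radius based.
A	67.0
R	148.0
N	96.0
D	91.0
C	86.0
E	109.0
Q	114.0
G	48.0
H	118.0
I	124.0
L	124.0
K	135.0
M	124.0
F	135.0
P	90.0
S	73.0
T	93.0
W	163.0
Y	141.0
V	105.0
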