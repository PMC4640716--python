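# Polarity, Grantham (1974).
A	8.1
R	10.5
N	11.6
D	13.0
C	5.5
E	12.3
Q	10.5
G	9.0
H	10.4
I	5.2
L	4.9
K	11.3
M	5.7
F	5.2
P	8.0
S	9.2
T	8.6
W	5.4
Y	6.2
V	5.9
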