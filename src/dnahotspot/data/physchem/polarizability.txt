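# Property: polarizability parameter
# Source: Charton & Charton (1982) J Theor Biol 99:629 (AAindex CHAM820101)
# aa  value
A 0.046
R 0.291
N 0.134
D 0.105
C 0.128
Q 0.180
E 0.151
G 0.000
H 0.230
I 0.186
L 0.186
K 0.219
M 0.221
F 0.290
P 0.131
S 0.062
T 0.108
W 0.409
Y 0.298
V 0.140
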