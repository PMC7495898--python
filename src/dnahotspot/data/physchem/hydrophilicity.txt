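# Property: hydrophilicity
# Source: Hopp & Woods (1981) PNAS 78:3824 (AAindex HOPT810101)
# aa  value
A -0.5
R 3.0
N 0.2
D 3.0
C -1.0
Q 0.2
E 3.0
G 0.0
H -0.5
I -1.8
L -1.8
K 3.0
M -1.3
F -2.5
P 0.0
S 0.3
T -0.4
W -3.4
Y -2.3
V -1.5
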