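# Property: average accessible surface area in folded proteins (A^2)
# Source: Janin et al. (1978)-style average accessibility scale
# aa  value
A 27.8
R 94.7
N 60.1
D 60.6
C 15.5
Q 68.7
E 68.2
G 24.5
H 50.7
I 22.8
L 27.6
K 103.0
M 33.5
F 25.5
P 51.5
S 42.0
T 45.0
W 34.7
Y 55.2
V 23.7
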