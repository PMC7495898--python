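# Property: alpha-helix propensity (conformational preference P_alpha)
# Source: Chou & Fasman (1978) Annu Rev Biochem 47:251 (AAindex-style scale)
# aa  value
A 1.42
R 0.98
N 0.67
D 1.01
C 0.70
Q 1.11
E 1.51
G 0.57
H 1.00
I 1.08
L 1.21
K 1.16
M 1.45
F 1.13
P 0.57
S 0.77
T 0.83
W 1.08
Y 0.69
V 1.06
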