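trackway,stature_m
A,1.53
B,1.66
C/G,1.47
D,1.83
E,1.78
EE,1.52
F,1.59
FF,1.47
H,1.80
I/T,1.62
J,1.58
K/DD,1.50
L/II,1.63
M,1.59
N/AA,1.48
O/Y,1.74
P,1.48
Q,1.57
R/BB,1.52
S/W,1.51
TT,1.35
U,1.48
V/CC,1.54
X,1.47
Z,1.40
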