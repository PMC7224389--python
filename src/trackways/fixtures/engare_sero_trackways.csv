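trackway,rsl,gait,velocity_mps,compass_dir,compass_deg,attribution,attribution_pct
A,5.69,Walk,1.42,NE,43,Adult female,70
B,8.58,Run,2.91,NE,46,Adult female,52
C/G,6.07,Walk,1.54,NE,46,Adult female,50
D,7.21,Walk,1.92,NE,49.5,Adult male,96
E,5.54,Walk,1.37,NE,43,Adult male,90
F,7.29,Walk,1.94,NE,49.5,Adult female,69
H,5.00,Walk,1.19,SW,235,Adult male,93
I/T,5.86,Walk,1.47,SW,226,Adult female,63
J,5.17,Walk,1.25,SW,218,Adult female,71
K/DD,5.45,Walk,1.34,SW,227,Adult female,61
L/II,5.23,Walk,1.27,SW,225,Adult female,57
M,5.01,Walk,1.20,SW,220,Adult female,69
N/AA,5.55,Walk,1.37,SW,228,Adult female,53
O/Y,5.19,Walk,1.26,SW,226,Adult male,83
P,5.46,Walk,1.34,SW,227,Adult female,52
Q,5.30,Walk,1.29,SW,225,Adult female,73
R/BB,5.32,Walk,1.30,SW,218.5,Adult female,70
S/W,5.41,Walk,1.33,SW,225,Adult female,65
U,5.56,Walk,1.38,SW,227,Adult female,55
V/CC,5.79,Walk,1.45,SW,226,Adult female,72
X,4.91,Walk,1.16,SW,233,Adult female,48
Z,5.31,Walk,1.30,SW,231,Juvenile male,45
EE,5.00,Walk,1.19,SW,,Adult female,69
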