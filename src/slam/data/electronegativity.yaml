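# Pauling electronegativities. An atom is "electropositive" (E bit of the
# DABE key) iff its own and all its contact neighbors' values are <= 2.5.
H: 2.20
D: 2.20
C: 2.55
N: 3.04
O: 3.44
F: 3.98
P: 2.19
S: 2.58
CL: 3.16
BR: 2.96
I: 2.66
SE: 2.55
B: 2.04
ZN: 1.65
MG: 1.31
NA: 0.93
K: 0.82
CA: 1.00
MN: 1.55
FE: 1.83
CU: 1.90
NI: 1.91
CO: 1.88
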