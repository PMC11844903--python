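# Mpipi residue table (charges scaled to +-0.75, H +0.375 as in the model
# publication; lambda unused for Wang-Frenkel models). SYNTHETIC STAND-IN:
# sigma/mass shared with the HPS table.
residue,q,lambda,sigma_nm,mass
A,0.0,0.0,0.504,71.0788
C,0.0,0.0,0.548,103.1388
D,-0.75,0.0,0.558,115.0886
E,-0.75,0.0,0.592,129.1155
F,0.0,0.0,0.636,147.1766
G,0.0,0.0,0.45,57.0519
H,0.375,0.0,0.608,137.1411
I,0.0,0.0,0.618,113.1594
K,0.75,0.0,0.636,128.1741
L,0.0,0.0,0.618,113.1594
M,0.0,0.0,0.618,131.1926
N,0.0,0.0,0.568,114.1038
P,0.0,0.0,0.556,97.1167
Q,0.0,0.0,0.602,128.1307
R,0.75,0.0,0.656,156.1875
S,0.0,0.0,0.518,87.0782
T,0.0,0.0,0.562,101.1051
V,0.0,0.0,0.586,99.1326
W,0.0,0.0,0.678,186.2132
Y,0.0,0.0,0.646,163.176
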