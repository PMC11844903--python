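# CALVADOS2 residue parameters: Bayesian-optimised stickiness scale,
# transcribed from the CALVADOS2 model publication.
residue,q,lambda,sigma_nm,mass
A,0.0,0.2743,0.504,71.0788
C,0.0,0.5615,0.548,103.1388
D,-1.0,0.0416,0.558,115.0886
E,-1.0,0.0006,0.592,129.1155
F,0.0,0.8672,0.636,147.1766
G,0.0,0.7058,0.45,57.0519
H,0.0,0.4663,0.608,137.1411
I,0.0,0.5423,0.618,113.1594
K,1.0,0.179,0.636,128.1741
L,0.0,0.644,0.618,113.1594
M,0.0,0.5308,0.618,131.1926
N,0.0,0.4255,0.568,114.1038
P,0.0,0.3593,0.556,97.1167
Q,0.0,0.3934,0.602,128.1307
R,1.0,0.7307,0.656,156.1875
S,0.0,0.4625,0.518,87.0782
T,0.0,0.3713,0.562,101.1051
V,0.0,0.2083,0.586,99.1326
W,0.0,0.9893,0.678,186.2132
Y,0.0,0.9774,0.646,163.176
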