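# SYNTHETIC STAND-IN Wang-Frenkel pair table (not the published fit).
# eps_ij = 0.85 kJ/mol * mean Urry lambda, x2.4 aromatic-aromatic,
# x3.2 R-aromatic, x1.6 K-aromatic; sigma_ij = mean bead diameter; nu = 1.
i,j,eps_kj,sigma_nm,nu
A,A,0.512501,0.504,1.0
A,C,0.53125,0.526,1.0
A,D,0.38125,0.531,1.0
A,E,0.25625,0.548,1.0
A,F,0.606251,0.57,1.0
A,G,0.500001,0.477,1.0
A,H,0.581251,0.556,1.0
A,I,0.556251,0.561,1.0
A,K,0.41875,0.57,1.0
A,L,0.562501,0.561,1.0
A,M,0.543751,0.561,1.0
A,N,0.506251,0.536,1.0
A,P,0.578751,0.53,1.0
A,Q,0.493751,0.553,1.0
A,R,0.493751,0.58,1.0
A,S,0.506251,0.511,1.0
A,T,0.506251,0.533,1.0
A,V,0.53875,0.545,1.0
A,W,0.68125,0.591,1.0
A,Y,0.6375,0.575,1.0
C,C,0.55,0.548,1.0
C,D,0.4,0.553,1.0
C,E,0.275,0.57,1.0
C,F,0.625,0.592,1.0
C,G,0.51875,0.499,1.0
C,H,0.600001,0.578,1.0
C,I,0.575,0.583,1.0
C,K,0.4375,0.592,1.0
C,L,0.58125,0.583,1.0
C,M,0.5625,0.583,1.0
C,N,0.525,0.558,1.0
C,P,0.5975,0.552,1.0
C,Q,0.5125,0.575,1.0
C,R,0.5125,0.602,1.0
C,S,0.525,0.533,1.0
C,T,0.525,0.555,1.0
C,V,0.5575,0.567,1.0
C,W,0.7,0.613,1.0
C,Y,0.65625,0.597,1.0
D,D,0.25,0.558,1.0
D,E,0.125,0.575,1.0
D,F,0.475,0.597,1.0
D,G,0.36875,0.504,1.0
D,H,0.450001,0.583,1.0
D,I,0.425,0.588,1.0
D,K,0.2875,0.597,1.0
D,L,0.43125,0.588,1.0
D,M,0.4125,0.588,1.0
D,N,0.375,0.563,1.0
D,P,0.4475,0.557,1.0
D,Q,0.3625,0.58,1.0
D,R,0.3625,0.607,1.0
D,S,0.375,0.538,1.0
D,T,0.375,0.56,1.0
D,V,0.4075,0.572,1.0
D,W,0.55,0.618,1.0
D,Y,0.50625,0.602,1.0
E,E,0.0,0.592,1.0
E,F,0.35,0.614,1.0
E,G,0.24375,0.521,1.0
E,H,0.325,0.6,1.0
E,I,0.3,0.605,1.0
E,K,0.1625,0.614,1.0
E,L,0.30625,0.605,1.0
E,M,0.2875,0.605,1.0
E,N,0.25,0.58,1.0
E,P,0.3225,0.574,1.0
E,Q,0.2375,0.597,1.0
E,R,0.2375,0.624,1.0
E,S,0.25,0.555,1.0
E,T,0.25,0.577,1.0
E,V,0.2825,0.589,1.0
E,W,0.425,0.635,1.0
E,Y,0.38125,0.619,1.0
F,F,1.680001,0.636,1.0
F,G,0.59375,0.543,1.0
F,H,0.675001,0.622,1.0
F,I,0.650001,0.627,1.0
F,K,0.82,0.636,1.0
F,L,0.656251,0.627,1.0
F,M,0.6375,0.627,1.0
F,N,0.600001,0.602,1.0
F,P,0.6725,0.596,1.0
F,Q,0.5875,0.619,1.0
F,R,1.880001,0.646,1.0
F,S,0.600001,0.577,1.0
F,T,0.600001,0.599,1.0
F,V,0.6325,0.611,1.0
F,W,1.860001,0.657,1.0
F,Y,1.755001,0.641,1.0
G,G,0.4875,0.45,1.0
G,H,0.568751,0.529,1.0
G,I,0.543751,0.534,1.0
G,K,0.40625,0.543,1.0
G,L,0.550001,0.534,1.0
G,M,0.53125,0.534,1.0
G,N,0.493751,0.509,1.0
G,P,0.56625,0.503,1.0
G,Q,0.48125,0.526,1.0
G,R,0.48125,0.553,1.0
G,S,0.493751,0.484,1.0
G,T,0.493751,0.506,1.0
G,V,0.52625,0.518,1.0
G,W,0.66875,0.564,1.0
G,Y,0.625,0.548,1.0
H,H,0.650001,0.608,1.0
H,I,0.625001,0.613,1.0
H,K,0.4875,0.622,1.0
H,L,0.631251,0.613,1.0
H,M,0.612501,0.613,1.0
H,N,0.575001,0.588,1.0
H,P,0.647501,0.582,1.0
H,Q,0.562501,0.605,1.0
H,R,0.562501,0.632,1.0
H,S,0.575001,0.563,1.0
H,T,0.575001,0.585,1.0
H,V,0.607501,0.597,1.0
H,W,0.75,0.643,1.0
H,Y,0.706251,0.627,1.0
I,I,0.600001,0.618,1.0
I,K,0.4625,0.627,1.0
I,L,0.606251,0.618,1.0
I,M,0.5875,0.618,1.0
I,N,0.550001,0.593,1.0
I,P,0.6225,0.587,1.0
I,Q,0.5375,0.61,1.0
I,R,0.5375,0.637,1.0
I,S,0.550001,0.568,1.0
I,T,0.550001,0.59,1.0
I,V,0.5825,0.602,1.0
I,W,0.725,0.648,1.0
I,Y,0.68125,0.632,1.0
K,K,0.325,0.636,1.0
K,L,0.46875,0.627,1.0
K,M,0.45,0.627,1.0
K,N,0.4125,0.602,1.0
K,P,0.485,0.596,1.0
K,Q,0.4,0.619,1.0
K,R,0.4,0.646,1.0
K,S,0.4125,0.577,1.0
K,T,0.4125,0.599,1.0
K,V,0.445,0.611,1.0
K,W,0.94,0.657,1.0
K,Y,0.87,0.641,1.0
L,L,0.612501,0.618,1.0
L,M,0.593751,0.618,1.0
L,N,0.556251,0.593,1.0
L,P,0.628751,0.587,1.0
L,Q,0.543751,0.61,1.0
L,R,0.543751,0.637,1.0
L,S,0.556251,0.568,1.0
L,T,0.556251,0.59,1.0
L,V,0.58875,0.602,1.0
L,W,0.73125,0.648,1.0
L,Y,0.6875,0.632,1.0
M,M,0.575,0.618,1.0
M,N,0.5375,0.593,1.0
M,P,0.61,0.587,1.0
M,Q,0.525,0.61,1.0
M,R,0.525,0.637,1.0
M,S,0.5375,0.568,1.0
M,T,0.5375,0.59,1.0
M,V,0.57,0.602,1.0
M,W,0.7125,0.648,1.0
M,Y,0.66875,0.632,1.0
N,N,0.500001,0.568,1.0
N,P,0.5725,0.562,1.0
N,Q,0.4875,0.585,1.0
N,R,0.4875,0.612,1.0
N,S,0.500001,0.543,1.0
N,T,0.500001,0.565,1.0
N,V,0.5325,0.577,1.0
N,W,0.675,0.623,1.0
N,Y,0.63125,0.607,1.0
P,P,0.645,0.556,1.0
P,Q,0.56,0.579,1.0
P,R,0.56,0.606,1.0
P,S,0.5725,0.537,1.0
P,T,0.5725,0.559,1.0
P,V,0.605,0.571,1.0
P,W,0.7475,0.617,1.0
P,Y,0.70375,0.601,1.0
Q,Q,0.475,0.602,1.0
Q,R,0.475,0.629,1.0
Q,S,0.4875,0.56,1.0
Q,T,0.4875,0.582,1.0
Q,V,0.52,0.594,1.0
Q,W,0.6625,0.64,1.0
Q,Y,0.61875,0.624,1.0
R,R,0.475,0.656,1.0
R,S,0.4875,0.587,1.0
R,T,0.4875,0.609,1.0
R,V,0.52,0.621,1.0
R,W,2.120001,0.667,1.0
R,Y,1.980001,0.651,1.0
S,S,0.500001,0.518,1.0
S,T,0.500001,0.54,1.0
S,V,0.5325,0.552,1.0
S,W,0.675,0.598,1.0
S,Y,0.63125,0.582,1.0
T,T,0.500001,0.562,1.0
T,V,0.5325,0.574,1.0
T,W,0.675,0.62,1.0
T,Y,0.63125,0.604,1.0
V,V,0.565,0.586,1.0
V,W,0.7075,0.632,1.0
V,Y,0.66375,0.616,1.0
W,W,2.04,0.678,1.0
W,Y,1.935,0.662,1.0
Y,Y,1.83,0.646,1.0
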