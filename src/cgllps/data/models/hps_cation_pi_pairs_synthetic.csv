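# SYNTHETIC STAND-IN cation-pi epsilon table for HPS-cation-pi (kJ/mol):
# uniform 3.0 kJ/mol for R/K x F/W/Y, the order of magnitude the model
# publication adopts; sigma from Lorentz-Berthelot mixing at evaluation time.
i,j,eps_kj
R,F,3.0
R,W,3.0
R,Y,3.0
K,F,3.0
K,W,3.0
K,Y,3.0
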