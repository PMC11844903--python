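# SYNTHETIC STAND-IN Yukawa amplitude table for Mpipi-Recharged (kJ nm/mol):
# screened-Coulomb scale at eps_r(298 K), x0.9 like-sign / x0.75 unlike-sign,
# hence symmetric in i<->j but not reducible to a product of charges.
i,j,A_kj_nm
D,D,1.593768
D,E,1.593768
D,K,-1.32814
D,R,-1.32814
E,E,1.593768
E,K,-1.32814
E,R,-1.32814
K,K,1.593768
K,R,1.593768
R,R,1.593768
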