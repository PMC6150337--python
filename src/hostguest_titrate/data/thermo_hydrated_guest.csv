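guest,host,dh_kJ_mol,ds_J_Kmol,dg_kJ_mol
alpha-ZOL,BCD,-37.6,-7.0,-35.6
alpha-ZOL,DIMEB,-46.6,-17.3,-41.5
alpha-ZOL,SBBCD,-39.6,-9.1,-36.9
beta-ZOL,BCD,-37.6,-7.0,-35.6
beta-ZOL,DIMEB,-33.8,6.9,-35.9
beta-ZOL,SBBCD,-41.6,-10.2,-38.6
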