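guest,host,dh_kJ_mol,ds_J_Kmol,dg_kJ_mol
alpha-ZOL,BCD,-23.4,34.6,-33.8
alpha-ZOL,DIMEB,-32.4,24.3,-39.7
alpha-ZOL,SBBCD,-25.4,32.5,-35.1
beta-ZOL,BCD,-23.4,34.6,-33.8
beta-ZOL,DIMEB,-19.6,48.5,-34.1
beta-ZOL,SBBCD,-27.4,31.4,-36.8
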