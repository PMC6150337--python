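guest,host,ea_kJ_mol
alpha-ZOL,BCD,-11.6
alpha-ZOL,DIMEB,-13.7
alpha-ZOL,SBBCD,-12.2
beta-ZOL,BCD,-11.9
beta-ZOL,DIMEB,-13.4
beta-ZOL,SBBCD,-22.2
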