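guest,host,log_k,se
ZEN,BCD,3.99,
ZEN,HPBCD,3.94,
ZEN,RAMEB,4.36,
ZEN,DIMEB,4.76,
ZEN,SBBCD,4.20,
ZEN,QABCD,3.75,
alpha-ZOL,BCD,3.90,0.01
alpha-ZOL,HPBCD,4.05,0.02
alpha-ZOL,RAMEB,4.59,0.04
alpha-ZOL,DIMEB,4.89,0.02
alpha-ZOL,SBBCD,4.58,0.00
alpha-ZOL,CMBCD,3.69,0.02
alpha-ZOL,QABCD,3.65,0.04
beta-ZOL,BCD,2.79,0.02
beta-ZOL,HPBCD,3.11,0.04
beta-ZOL,RAMEB,3.68,0.01
beta-ZOL,DIMEB,3.88,0.00
beta-ZOL,SBBCD,3.64,0.02
beta-ZOL,CMBCD,2.65,0.05
beta-ZOL,QABCD,2.25,0.09
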