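guest,host,log_beta,se
alpha-ZOL,BCD,4.03,0.04
alpha-ZOL,HPBCD,4.21,0.01
alpha-ZOL,RAMEB,4.74,0.01
alpha-ZOL,DIMEB,5.00,0.01
alpha-ZOL,SBBCD,4.68,0.01
alpha-ZOL,CMBCD,3.92,0.02
alpha-ZOL,QABCD,3.88,0.02
beta-ZOL,BCD,3.08,0.01
beta-ZOL,HPBCD,3.41,0.02
beta-ZOL,RAMEB,3.82,0.02
beta-ZOL,DIMEB,4.02,0.02
beta-ZOL,SBBCD,3.85,0.02
beta-ZOL,CMBCD,3.07,0.01
beta-ZOL,QABCD,2.64,0.01
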