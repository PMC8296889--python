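scenario,parameter,weight
S1,pH,0.05
S1,TDS,0.11
S1,TSS,0.11
S1,BOD5,0.09
S1,COD,0.09
S1,NH3-N,0.09
S1,NO3-N,0.17
S1,PO4-P,0.17
S1,Cl2,0.03
S1,TC,0.04
S1,FC,0.04
S2,pH,0.06
S2,TDS,0.09
S2,TSS,0.08
S2,BOD5,0.07
S2,COD,0.07
S2,NH3-N,0.07
S2,NO3-N,0.13
S2,PO4-P,0.13
S2,Cl2,0.07
S2,TC,0.10
S2,FC,0.10
S3,pH,0.06
S3,TDS,0.09
S3,TSS,0.07
S3,BOD5,0.07
S3,COD,0.07
S3,NH3-N,0.07
S3,NO3-N,0.11
S3,PO4-P,0.11
S3,Cl2,0.10
S3,TC,0.12
S3,FC,0.12
S4,pH,0.07
S4,TDS,0.07
S4,TSS,0.08
S4,BOD5,0.07
S4,COD,0.07
S4,NH3-N,0.07
S4,NO3-N,0.11
S4,PO4-P,0.11
S4,Cl2,0.10
S4,TC,0.12
S4,FC,0.12
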