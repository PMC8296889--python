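scenario,facility,parameter,p
S1,WWTP-1,pH,99.75
S1,WWTP-1,TDS,99.50
S1,WWTP-1,TSS,99.75
S1,WWTP-1,BOD5,99.75
S1,WWTP-1,COD,99.75
S1,WWTP-1,NH3-N,98.24
S1,WWTP-1,NO3-N,99.75
S1,WWTP-1,PO4-P,99.75
S1,WWTP-1,Cl2,0.50
S1,WWTP-1,TC,99.99
S1,WWTP-1,FC,99.99
S1,WWTP-2,pH,99.81
S1,WWTP-2,TDS,99.81
S1,WWTP-2,TSS,99.81
S1,WWTP-2,BOD5,99.39
S1,WWTP-2,COD,99.81
S1,WWTP-2,NH3-N,99.81
S1,WWTP-2,NO3-N,99.81
S1,WWTP-2,PO4-P,99.23
S1,WWTP-2,Cl2,0.01
S1,WWTP-2,TC,99.99
S1,WWTP-2,FC,99.99
S1,WWTP-3,pH,99.73
S1,WWTP-3,TDS,99.73
S1,WWTP-3,TSS,99.73
S1,WWTP-3,BOD5,98.89
S1,WWTP-3,COD,99.16
S1,WWTP-3,NH3-N,99.73
S1,WWTP-3,NO3-N,99.73
S1,WWTP-3,PO4-P,99.45
S1,WWTP-3,Cl2,0.01
S1,WWTP-3,TC,99.99
S1,WWTP-3,FC,99.99
S1,WWTP-4,pH,99.73
S1,WWTP-4,TDS,99.73
S1,WWTP-4,TSS,99.73
S1,WWTP-4,BOD5,99.73
S1,WWTP-4,COD,99.73
S1,WWTP-4,NH3-N,99.73
S1,WWTP-4,NO3-N,99.73
S1,WWTP-4,PO4-P,96.72
S1,WWTP-4,Cl2,15.03
S1,WWTP-4,TC,99.99
S1,WWTP-4,FC,99.99
S2,WWTP-1,pH,99.75
S2,WWTP-1,TDS,98.99
S2,WWTP-1,TSS,99.75
S2,WWTP-1,BOD5,99.75
S2,WWTP-1,COD,99.75
S2,WWTP-1,NH3-N,98.24
S2,WWTP-1,NO3-N,99.75
S2,WWTP-1,PO4-P,99.75
S2,WWTP-1,Cl2,0.50
S2,WWTP-1,TC,99.99
S2,WWTP-1,FC,99.99
S2,WWTP-2,pH,99.81
S2,WWTP-2,TDS,99.81
S2,WWTP-2,TSS,99.81
S2,WWTP-2,BOD5,99.39
S2,WWTP-2,COD,99.81
S2,WWTP-2,NH3-N,99.81
S2,WWTP-2,NO3-N,99.81
S2,WWTP-2,PO4-P,99.23
S2,WWTP-2,Cl2,0.01
S2,WWTP-2,TC,99.99
S2,WWTP-2,FC,99.99
S2,WWTP-3,pH,99.73
S2,WWTP-3,TDS,99.73
S2,WWTP-3,TSS,99.73
S2,WWTP-3,BOD5,98.89
S2,WWTP-3,COD,99.16
S2,WWTP-3,NH3-N,99.73
S2,WWTP-3,NO3-N,99.73
S2,WWTP-3,PO4-P,99.45
S2,WWTP-3,Cl2,0.01
S2,WWTP-3,TC,99.99
S2,WWTP-3,FC,99.99
S2,WWTP-4,pH,99.73
S2,WWTP-4,TDS,99.73
S2,WWTP-4,TSS,99.73
S2,WWTP-4,BOD5,99.73
S2,WWTP-4,COD,99.73
S2,WWTP-4,NH3-N,99.73
S2,WWTP-4,NO3-N,99.73
S2,WWTP-4,PO4-P,96.72
S2,WWTP-4,Cl2,15.03
S2,WWTP-4,TC,99.99
S2,WWTP-4,FC,99.99
S3,WWTP-1,pH,99.75
S3,WWTP-1,TDS,74.06
S3,WWTP-1,TSS,99.75
S3,WWTP-1,BOD5,97.98
S3,WWTP-1,COD,99.75
S3,WWTP-1,NH3-N,85.14
S3,WWTP-1,NO3-N,99.75
S3,WWTP-1,PO4-P,1.76
S3,WWTP-1,Cl2,0.50
S3,WWTP-1,TC,99.99
S3,WWTP-1,FC,99.99
S3,WWTP-2,pH,99.81
S3,WWTP-2,TDS,99.61
S3,WWTP-2,TSS,99.81
S3,WWTP-2,BOD5,94.51
S3,WWTP-2,COD,99.81
S3,WWTP-2,NH3-N,99.81
S3,WWTP-2,NO3-N,99.81
S3,WWTP-2,PO4-P,0.01
S3,WWTP-2,Cl2,0.01
S3,WWTP-2,TC,99.99
S3,WWTP-2,FC,99.99
S3,WWTP-3,pH,99.73
S3,WWTP-3,TDS,99.45
S3,WWTP-3,TSS,99.45
S3,WWTP-3,BOD5,73.33
S3,WWTP-3,COD,99.16
S3,WWTP-3,NH3-N,93.44
S3,WWTP-3,NO3-N,99.73
S3,WWTP-3,PO4-P,6.56
S3,WWTP-3,Cl2,0.01
S3,WWTP-3,TC,99.99
S3,WWTP-3,FC,99.99
S3,WWTP-4,pH,99.73
S3,WWTP-4,TDS,99.73
S3,WWTP-4,TSS,99.45
S3,WWTP-4,BOD5,69.67
S3,WWTP-4,COD,99.73
S3,WWTP-4,NH3-N,99.45
S3,WWTP-4,NO3-N,99.73
S3,WWTP-4,PO4-P,0.01
S3,WWTP-4,Cl2,15.03
S3,WWTP-4,TC,99.99
S3,WWTP-4,FC,99.99
S4,WWTP-1,pH,97.98
S4,WWTP-1,TDS,0.005
S4,WWTP-1,TSS,99.75
S4,WWTP-1,BOD5,72.29
S4,WWTP-1,COD,99.75
S4,WWTP-1,NH3-N,83.63
S4,WWTP-1,NO3-N,99.75
S4,WWTP-1,PO4-P,1.76
S4,WWTP-1,Cl2,0.50
S4,WWTP-1,TC,99.99
S4,WWTP-1,FC,99.99
S4,WWTP-2,pH,98.84
S4,WWTP-2,TDS,0.008
S4,WWTP-2,TSS,99.81
S4,WWTP-2,BOD5,60.37
S4,WWTP-2,COD,99.81
S4,WWTP-2,NH3-N,99.81
S4,WWTP-2,NO3-N,0.19
S4,WWTP-2,PO4-P,0.01
S4,WWTP-2,Cl2,0.01
S4,WWTP-2,TC,99.99
S4,WWTP-2,FC,99.99
S4,WWTP-3,pH,98.91
S4,WWTP-3,TDS,0.009
S4,WWTP-3,TSS,99.45
S4,WWTP-3,BOD5,37.78
S4,WWTP-3,COD,88.24
S4,WWTP-3,NH3-N,92.62
S4,WWTP-3,NO3-N,99.73
S4,WWTP-3,PO4-P,6.56
S4,WWTP-3,Cl2,0.01
S4,WWTP-3,TC,99.99
S4,WWTP-3,FC,99.99
S4,WWTP-4,pH,99.73
S4,WWTP-4,TDS,0.010
S4,WWTP-4,TSS,99.45
S4,WWTP-4,BOD5,3.01
S4,WWTP-4,COD,99.45
S4,WWTP-4,NH3-N,99.45
S4,WWTP-4,NO3-N,98.09
S4,WWTP-4,PO4-P,0.01
S4,WWTP-4,Cl2,15.03
S4,WWTP-4,TC,99.99
S4,WWTP-4,FC,99.99
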