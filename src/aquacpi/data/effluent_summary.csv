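facility,parameter,unit,min,mean,max,sd,cv
WWTP-1,TDS,mg/L,1078,1469,3263,152,10.3
WWTP-1,TSS,mg/L,1.0,1.0,2.0,0.1,9.9
WWTP-1,pH,-,6.9,7.3,8.4,0.2,2.9
WWTP-1,BOD5,mg/L,1.0,2.7,7.7,0.9,32.1
WWTP-1,COD,mg/L,5.4,9.3,20.0,2.7,28.8
WWTP-1,NH3-N,mg/L,0.0,0.5,6.4,1.2,248.8
WWTP-1,NO3-N,mg/L,0.4,2.3,4.9,0.9,38.3
WWTP-1,PO4-P,mg/L,1.2,5.4,8.2,1.2,22.6
WWTP-1,Cl2,mg/L,0.3,0.7,3.8,0.3,34.4
WWTP-1,TC,MPN/100mL,<1,<1,<1,<1,-
WWTP-1,FC,MPN/100mL,<1,<1,<1,<1,-
WWTP-2,TDS,mg/L,673,776,1987,101,13
WWTP-2,TSS,mg/L,1.0,1.0,1.0,0.2,20.4
WWTP-2,pH,-,6.7,7.2,8.3,0.3,3.6
WWTP-2,BOD5,mg/L,0.7,2.8,6.3,1.2,42.6
WWTP-2,COD,mg/L,8.0,10.9,17.0,1.8,16.6
WWTP-2,NH3-N,mg/L,0,0,0,0,-
WWTP-2,NO3-N,mg/L,6.3,8.5,9.6,0.5,6.1
WWTP-2,PO4-P,mg/L,3.0,4.4,11.0,1.4,31.5
WWTP-2,Cl2,mg/L,0.5,0.9,3.9,0.3,28.1
WWTP-2,TC,MPN/100mL,<1,<1,<1,<1,-
WWTP-2,FC,MPN/100mL,<1,<1,<1,<1,-
WWTP-3,TDS,mg/L,877,936,1759,75,8.0
WWTP-3,TSS,mg/L,1.0,1.3,7.0,0.7,51.7
WWTP-3,pH,-,7.0,7.2,8.2,0.2,2.5
WWTP-3,BOD5,mg/L,0.5,3.7,8.1,1.9,52.5
WWTP-3,COD,mg/L,4.0,17.7,39.0,5.9,33.4
WWTP-3,NH3-N,mg/L,0.0,0.2,5.0,0.8,357.6
WWTP-3,NO3-N,mg/L,1.1,3.7,4.7,0.6,15.8
WWTP-3,PO4-P,mg/L,1.8,4.6,11.4,1.2,27.0
WWTP-3,Cl2,mg/L,0.5,0.9,4.0,0.3,34.3
WWTP-3,TC,MPN/100mL,<1,<1,<1,<1,-
WWTP-3,FC,MPN/100mL,<1,<1,<1,<1,-
WWTP-4,TDS,mg/L,823,872,1152,43.7,5.0
WWTP-4,TSS,mg/L,1.0,2.1,6.0,0.5,23.2
WWTP-4,pH,-,6.5,7.0,7.6,0.1,1.7
WWTP-4,BOD5,mg/L,2.8,5.0,6.6,0.6,12.7
WWTP-4,COD,mg/L,14.0,18.5,33.0,1.8,9.6
WWTP-4,NH3-N,mg/L,0.0,0.1,0.8,0.1,46.4
WWTP-4,NO3-N,mg/L,6.0,6.3,8.0,0.5,8.0
WWTP-4,PO4-P,mg/L,6.0,7.5,12.5,1.0,13.2
WWTP-4,Cl2,mg/L,0.5,0.7,2.6,0.2,29.7
WWTP-4,TC,MPN/100mL,<1,<1,<1,<1,-
WWTP-4,FC,MPN/100mL,<1,<1,<1,<1,-
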