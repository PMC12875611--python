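condition,N,regress,bump,limb
AntBL,8,3,5,0
AntBL + P,9,0,1,8
PostBL,8,6,2,0
PostBL + A,7,2,1,4
DorBL,12,8,3,1
DorBL + V,14,5,2,7
VentBL,22,15,7,0
VentBL + D,11,2,2,7
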