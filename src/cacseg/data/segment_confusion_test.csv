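reference,p-RCA,m-RCA,d-RCA,s-RCA,LM,p-LAD,m-LAD,d-LAD,s-LAD,p-LCX,m-LCX,d-LCX,s-LCX
p-RCA,300,17,0,0,0,0,0,1,1,0,0,0,0
m-RCA,31,62,13,0,0,0,0,0,0,0,0,0,0
d-RCA,3,6,134,0,0,0,0,0,0,0,0,2,0
s-RCA,4,6,0,0,0,0,0,0,0,0,0,0,0
LM,0,0,0,0,79,24,0,0,1,6,0,0,0
p-LAD,0,0,0,0,26,204,49,0,6,1,0,0,0
m-LAD,0,0,0,0,0,74,123,18,15,0,0,0,0
d-LAD,0,0,0,0,0,5,48,59,5,0,0,0,1
s-LAD,0,0,0,0,4,14,11,5,102,4,0,0,1
p-LCX,1,0,1,0,20,0,0,0,5,177,8,0,9
m-LCX,0,0,0,0,0,0,0,0,0,4,17,0,7
d-LCX,0,0,6,0,0,0,0,0,0,0,0,14,0
s-LCX,0,0,1,0,0,0,0,0,0,10,7,0,45
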