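reference,I,II,III,IV
I,162,30,2,0
II,2,113,5,1
III,0,1,62,3
IV,0,1,0,73
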