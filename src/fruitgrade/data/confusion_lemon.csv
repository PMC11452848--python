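grade,1,2,3,4
1,15,2,0,0
2,1,15,1,0
3,0,1,15,1
4,0,0,0,17
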