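grade,1,2,3,4
1,18,2,0,0
2,4,16,0,0
3,0,1,17,2
4,0,0,0,20
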