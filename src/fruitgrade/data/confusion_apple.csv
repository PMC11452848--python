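grade,1,2,3,4
1,32,8,0,0
2,4,28,4,4
3,0,4,28,8
4,0,4,8,28
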