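code,recoded
0,0
1,1
2,2
3,3
4,4
5,4
6,4
8,4
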