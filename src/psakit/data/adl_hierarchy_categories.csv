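code,category
0,0
1,0
2,1
3,1
4,2
5,2
6,3
8,3
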