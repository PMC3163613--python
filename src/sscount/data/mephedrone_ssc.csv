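total,count
0,15
1,64
2,89
3,51
4,16
5,2
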