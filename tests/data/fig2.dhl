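%dihyper v1 nodes=9
0	one_way	tail:1,2	head:0
1	one_way	tail:3	head:4,5,6
2	one_way	tail:6,7	head:0,8
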