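%dihyper v1 nodes=5
0	one_way	tail:1,2,3	head:0
1	mutual	tail:1	head:4
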