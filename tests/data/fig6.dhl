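%dihyper v1 nodes=13
0	mutual	tail:4,5	head:9
1	one_way	tail:11,12	head:9,10
2	one_way	tail:4	head:3
3	one_way	tail:11	head:4
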