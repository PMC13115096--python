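%dihyper v1 nodes=9
0	one_way	tail:1,2,3	head:0
1	mutual	tail:1	head:4
2	one_way	tail:5	head:0,2
3	one_way	tail:6	head:1,3
4	one_way	tail:7,8	head:0
5	one_way	tail:8	head:3
6	mutual	tail:7	head:6
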