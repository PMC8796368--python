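chrom,genes_per_mb
1,8.5
2,5.2
3,5.4
4,4.0
5,4.9
6,5.9
7,6.0
8,4.8
9,5.8
10,5.6
11,9.5
12,7.8
13,3.4
14,5.7
15,6.5
16,9.9
17,14.6
18,3.8
19,24.9
20,8.9
21,5.1
22,9.7
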