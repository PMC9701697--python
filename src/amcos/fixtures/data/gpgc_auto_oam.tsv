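cutoff	sensitivity	one_minus_specificity
3.00	1.000	1.000
4.50	1.000	0.962
5.50	1.000	0.923
6.50	0.962	0.769
7.50	0.962	0.615
8.50	0.923	0.462
9.50	0.885	0.350
10.50	0.654	0.154
11.50	0.577	0.038
12.50	0.385	0.038
13.50	0.192	0.000
15.00	0.000	0.000
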