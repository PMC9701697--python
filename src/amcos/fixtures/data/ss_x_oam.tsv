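cutoff	sensitivity	one_minus_specificity
1.00	1.000	1.000
3.00	1.000	0.900
4.50	1.000	0.800
5.50	1.000	0.550
6.50	1.000	0.450
7.50	1.000	0.150
8.50	1.000	0.100
9.50	1.000	0.050
10.50	1.000	0.000
11.50	0.850	0.000
13.00	0.000	0.000
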