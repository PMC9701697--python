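cutoff	sensitivity	one_minus_specificity
-1.00	1.000	1.000
0.50	1.000	0.950
1.50	1.000	0.600
2.50	1.000	0.200
3.50	1.000	0.100
4.50	1.000	0.000
5.50	0.950	0.000
6.50	0.900	0.000
7.50	0.800	0.000
8.50	0.550	0.000
9.50	0.450	0.000
10.50	0.250	0.000
11.50	0.200	0.000
13.00	0.000	0.000
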