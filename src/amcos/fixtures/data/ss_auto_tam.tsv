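cutoff	sensitivity	one_minus_specificity
-1.00	1.000	1.000
0.50	1.000	0.650
1.50	1.000	0.300
2.50	0.950	0.000
3.50	0.850	0.000
4.50	0.750	0.000
5.50	0.550	0.000
6.50	0.250	0.000
7.50	0.100	0.000
9.00	0.000	0.000
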