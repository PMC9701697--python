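cutoff	sensitivity	one_minus_specificity
-1.00	1.000	1.000
0.50	0.960	0.600
1.50	0.960	0.200
2.50	0.920	0.000
3.50	0.520	0.000
4.50	0.320	0.000
5.50	0.120	0.000
7.00	0.080	0.000
9.00	0.000	0.000
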