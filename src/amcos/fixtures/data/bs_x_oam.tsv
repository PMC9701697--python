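cutoff	sensitivity	one_minus_specificity
1.00	1.000	1.000
2.50	1.000	0.880
3.50	0.880	0.760
4.50	0.840	0.320
5.50	0.800	0.240
6.50	0.680	0.040
7.50	0.560	0.000
8.50	0.520	0.000
9.50	0.360	0.000
10.50	0.160	0.000
11.50	0.080	0.000
13.00	0.000	0.000
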