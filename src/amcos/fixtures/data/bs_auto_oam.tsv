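cutoff	sensitivity	one_minus_specificity
3.00	1.000	1.000
4.50	1.000	0.960
5.50	1.000	0.880
6.50	0.800	0.800
7.50	0.720	0.480
8.50	0.520	0.280
9.50	0.400	0.080
10.50	0.160	0.000
11.50	0.040	0.000
13.00	0.000	0.000
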