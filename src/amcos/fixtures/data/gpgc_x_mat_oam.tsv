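cutoff	sensitivity	one_minus_specificity
-1.00	1.000	1.000
0.50	1.000	0.923
1.50	1.000	0.846
2.50	1.000	0.769
3.50	1.000	0.308
4.50	0.846	0.231
5.50	0.846	0.077
6.50	0.769	0.000
8.00	0.692	0.000
9.50	0.462	0.000
10.50	0.385	0.000
11.50	0.154	0.000
13.00	0.000	0.000
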