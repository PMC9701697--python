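cutoff	sensitivity	one_minus_specificity
4.00	1.000	1.000
5.50	1.000	0.857
6.50	1.000	0.571
7.50	1.000	0.143
10.00	1.000	0.000
13.00	0.000	0.000
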