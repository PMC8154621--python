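compound	polarity	dE_S0S1_eV	f_S0S1	delta_S0S1_1e4au	delta2SM_S0S1_1e4au	dE_S0S2_eV	f_S0S2	delta_S0S2_1e4au	delta3SM_S0S2_1e4au
1	quadrupolar	3.28	0.99	0.00		4.16	0.00	1.36
2	quadrupolar	3.09	1.07	0.00		4.13	0.00	1.70	2.25
3	dipolar	3.00	1.24	0.12		3.74	0.05	2.78	3.71
4	dipolar	2.96	1.38	0.37		3.64	0.07	4.71	6.64
5	dipolar	2.92	1.37	1.02		3.54	0.12	6.49	8.63
6	quadrupolar	2.92	1.43	0.00		3.57	0.00	5.78	9.44
7	quadrupolar	2.84	1.74	0.00		3.40	0.00	11.93	21.34
8	quadrupolar	2.79	1.79	0.00		3.28	0.00	18.39	32.99
9	quadrupolar	2.62	1.97	0.00		3.20	0.00	40.94	43.90
10	dipolar	2.70	1.29	9.44	12.90	3.27	0.47	12.20	13.94
11	quadrupolar	3.04	1.20	0.00		3.88	0.00	2.02
12	dipolar	2.72	1.24	6.69	9.28	3.18	0.51	9.16
13	quadrupolar	2.78	1.19	0.00		2.94	0.00	0.90
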