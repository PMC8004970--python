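case	opia_sum	log10_cpi_snp	log10_cpi_astr
1	22	2.91	3.82
2	27	2.65	3.47
3	23	1.78	3.96
4	25	3.86	4.48
5	25	3.74	6.25
6	20	3.08	0.17
7	19	1.47	2.95
8	18	3.92	2.34
9	29	6.27	3.76
10	21	3.50	2.38
11	15	1.79	3.68
12	21	3.39	4.78
13	28	2.63	4.47
14	3	0.28	-0.64
15	21	2.24	0.70
16	32	4.42	5.08
17	35	4.60	8.86
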