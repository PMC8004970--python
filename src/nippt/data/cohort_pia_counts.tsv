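case	snp_epia	snp_opia	snp_fp	astr_epia	astr_opia	astr_fp	xstr_epia	xstr_opia	xstr_fp	ystr_epia	ystr_opia
1	18	14	0	21	8	1	2	1	1	0	0
2	21	16	0	21	11	2	0	0	0	27	11
3	21	14	0	20	9	2	3	0	0	0	0
4	17	15	0	19	10	0	4	2	1	0	0
5	19	16	0	18	9	0	1	1	0	0	0
6	18	14	0	19	6	3	4	0	0	0	0
7	10	9	0	16	10	3	3	1	1	0	0
8	17	14	0	14	4	0	2	1	1	0	0
9	19	19	1	16	10	2	4	1	0	0	0
10	16	14	0	14	7	2	4	0	0	0	0
11	15	9	0	16	6	1	3	2	2	0	0
12	20	14	0	11	7	0	3	1	0	0	0
13	22	18	0	17	10	2	3	3	2	0	0
14	21	1	0	15	2	1	2	0	0	0	0
15	19	14	0	17	7	3	3	1	0	0	0
16	22	21	0	13	11	1	0	0	0	27	15
17	18	18	0	19	17	0	2	2	0	0	0
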