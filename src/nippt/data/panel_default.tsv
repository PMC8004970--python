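locus_id	marker_class	chromosome	amplicon_length	motif_structure
rs1000000	iiSNP	1	135	
rs1010044	iiSNP	2	193	
rs1020162	iiSNP	3	80	
rs1030354	iiSNP	4	132	
rs1040620	iiSNP	5	138	
rs1050960	iiSNP	6	86	
rs1061374	iiSNP	7	120	
rs1071862	iiSNP	8	90	
rs1082424	iiSNP	9	134	
rs1093060	iiSNP	10	117	
rs1103770	iiSNP	11	155	
rs1114554	iiSNP	12	207	
rs1125412	iiSNP	13	100	
rs1136344	iiSNP	14	78	
rs1147350	iiSNP	15	130	
rs1158430	iiSNP	16	142	
rs1169584	iiSNP	17	148	
rs1170839	iiSNP	18	124	
rs1182141	iiSNP	19	102	
rs1193517	iiSNP	20	214	
rs1204967	iiSNP	21	111	
rs1216491	iiSNP	22	104	
rs1228089	iiSNP	1	131	
rs1239761	iiSNP	2	127	
rs1241534	iiSNP	3	116	
rs1253354	iiSNP	4	179	
rs1265248	iiSNP	5	97	
rs1277216	iiSNP	6	126	
rs1289258	iiSNP	7	91	
rs1291401	iiSNP	8	70	
rs1303591	iiSNP	9	96	
rs1315855	iiSNP	10	113	
rs1328193	iiSNP	11	172	
rs1330632	iiSNP	12	152	
rs1343118	iiSNP	13	73	
rs1355678	iiSNP	14	95	
rs1368312	iiSNP	15	115	
rs1371047	iiSNP	16	93	
rs1383829	iiSNP	17	157	
rs1396685	iiSNP	18	141	
rs1409615	iiSNP	19	71	
rs1412646	iiSNP	20	149	
rs1425724	iiSNP	21	81	
rs1438876	iiSNP	22	159	
rs1442129	iiSNP	1	76	
rs1455429	iiSNP	2	72	
rs1468803	iiSNP	3	98	
rs1472278	iiSNP	4	108	
rs1485800	iiSNP	5	99	
rs1499396	iiSNP	6	85	
rs1503093	iiSNP	7	156	
rs1516837	iiSNP	8	109	
rs1520682	iiSNP	9	105	
rs1534574	iiSNP	10	151	
rs1548540	iiSNP	11	94	
rs1552607	iiSNP	12	106	
rs1566721	iiSNP	13	84	
rs1570936	iiSNP	14	144	
rs1585198	iiSNP	15	112	
rs1599534	iiSNP	16	137	
rs1603971	iiSNP	17	125	
rs1618455	iiSNP	18	88	
rs1623040	iiSNP	19	79	
rs1637672	iiSNP	20	133	
rs1642405	iiSNP	21	75	
rs1657185	iiSNP	22	140	
rs1662066	iiSNP	1	200	
rs1676994	iiSNP	2	165	
rs1682023	iiSNP	3	128	
rs1697099	iiSNP	4	129	
rs1702276	iiSNP	5	77	
rs1717500	iiSNP	6	123	
rs1722825	iiSNP	7	89	
rs1738197	iiSNP	8	83	
rs1743670	iiSNP	9	82	
rs1759190	iiSNP	10	139	
rs1764811	iiSNP	11	110	
rs1780479	iiSNP	12	103	
rs1786248	iiSNP	13	87	
rs1792091	iiSNP	14	122	
rs1807981	iiSNP	15	150	
rs1813972	iiSNP	16	186	
rs1830010	iiSNP	17	147	
rs1836149	iiSNP	18	101	
rs1842362	iiSNP	19	121	
rs1858622	iiSNP	20	146	
rs1864983	iiSNP	21	74	
rs1871418	iiSNP	22	154	
rs1887900	iiSNP	1	143	
rs1894483	iiSNP	2	145	
rs1901140	iiSNP	3	118	
rs1917844	iiSNP	4	153	
rs1924649	iiSNP	5	119	
rs1931528	iiSNP	6	107	
CSF1PO	A-STR	5	185	AGAT*
D1S1656	A-STR	1	153	TAGA*
D2S441	A-STR	2	130	TCTA*
D2S1338	A-STR	2	124	GGAA*|GGCA*
D3S1358	A-STR	3	141	TCTA*|TCTG*
D4S2408	A-STR	4	110	ATCT*
D5S818	A-STR	5	270	AGAT*
D6S1043	A-STR	6	150	AGAT*
D7S820	A-STR	7	144	GATA*
D8S1179	A-STR	8	168	TCTA*|TCTG*
D9S1122	A-STR	9	136	TAGA*
D10S1248	A-STR	10	159	GGAA*
D12S391	A-STR	12	119	AGAT*|AGAC*
D13S317	A-STR	13	139	TATC*
D16S539	A-STR	16	205	GATA*
D17S1301	A-STR	17	228	AGAT*
D18S51	A-STR	18	113	AGAA*
D19S433	A-STR	19	156	AAGG*
D20S482	A-STR	20	107	AGAT*
D21S11	A-STR	21	147	TCTA*|TCTG*|TCTA*
D22S1045	A-STR	22	104	ATT*
FGA	A-STR	4	127	TTTC*|TTCC|TTTC*
PentaD	A-STR	21	121	AAAGA*
PentaE	A-STR	15	133	AAAGA*
TH01	A-STR	11	102	AATG*
TPOX	A-STR	2	116	AATG*
vWA	A-STR	12	252	TCTA*|TCTG*
DXS10074	X-STR	X	254	AAGA*
DXS10103	X-STR	X	198	TAGA*
DXS10135	X-STR	X	152	GAAA*
DXS7132	X-STR	X	283	TCTA*
DXS7423	X-STR	X	172	TCCA*
DXS8378	X-STR	X	312	CTAT*
HPRTB	X-STR	X	226	AGAT*
DYS19	Y-STR	Y	148	TAGA*
DYS385a-b	Y-STR	Y	297	GAAA*
DYS389I	Y-STR	Y	209	TCTG*|TCTA*
DYS389II	Y-STR	Y	231	TCTG*|TCTA*
DYS390	Y-STR	Y	154	TCTA*|TCTG*
DYS391	Y-STR	Y	264	TCTA*
DYS392	Y-STR	Y	112	TAT*
DYS393	Y-STR	Y	275	AGAT*
DYS437	Y-STR	Y	330	TCTA*
DYS438	Y-STR	Y	142	TTTTC*
DYS439	Y-STR	Y	118	AGAT*
DYS448	Y-STR	Y	136	AGAGAT*
DYS460	Y-STR	Y	220	ATAG*
DYS481	Y-STR	Y	198	CTT*
DYS505	Y-STR	Y	165	TCCT*
DYS522	Y-STR	Y	187	ATAG*
DYS533	Y-STR	Y	253	ATCT*
DYS549	Y-STR	Y	308	GATA*
DYS570	Y-STR	Y	319	TTTC*
DYS576	Y-STR	Y	130	AAAG*
DYS612	Y-STR	Y	124	CCT*
DYS635	Y-STR	Y	176	TCTA*
DYS643	Y-STR	Y	242	CTTTT*
Y-GATA-H4	Y-STR	Y	286	TAGA*
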