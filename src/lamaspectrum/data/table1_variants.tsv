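source_row	region_label	cdna	protein	allele_count	acmg_codes	db_id
1	54	c.7536del	p.(Asp2513IlefsTer34)	27	.	CD2117468
2	32	c.4692_4695dup	p.(Arg1566CysfsTer13)	16	.	CI054467
3	Intron 58	c.8245-2A>G	p.?	12	.	CS1311884
4	36	c.5116C>T	p.(Arg1706Ter)	10	.	CM981165
5	14	c.2049_2050del	p.(Arg683SerfsTer21)	9	.	CD982727
6	55	c.7732C>T	p.(Arg2578Ter)	5	.	CM032280
7	26	c.3829C>T	p.(Arg1277Ter)	4	.	CM1816718
8	50	c.7147C>T	p.(Arg2383Ter)	4	.	CM004723
9	65	c.9235_9238dup	p.(Thr3080AsnfsTer26)	4	.	CI102066
10	49	c.6955C>T	p.(Arg2319Ter)	3	.	CM981166
11	Intron 49	c.6992+1G>T	p.?	3	PM2;PVS1;PP4	.
12	Intron 49	c.6993-2A>C	p.?	3	.	CS085942
13	22	c.3085C>T	p.(Arg1029Ter)	3	.	CM020725
14	46	c.6466C>T	p.(Arg2156Ter)	3	.	CM142796
15	54	c.7520del	p.(Asn2507IlefsTer40)	3	PM2;PVS1;PM3;PP4	.
16	2	c.163A>C	p.(Asn55His)	2	PM2;PP3;PM3;PP4	.
17	Intron 2	c.283+1G>A	p.?	2	.	CS102090
18	9	c.1303C>T	p.(Arg435Ter)	2	.	CM102052
19	11	c.1522C>T	p.(Gln508Ter)	2	.	CM2136520
20	14	c.1893_1897del	p.(Asp631GlufsTer8)	2	.	CD021018
21	15	c.2184_2185del	p.(Gly729ValfsTer7)	2	PM2;PVS1	.
22	14	del ex 14	p.?	2	PM2;PVS1	.
23	32	c.4706G>A	p.(Trp1569Ter)	2	PM2;PVS1	.
24	Intron 35	c.5071+1G>A	p.?	2	.	CS151383
25	36	c.5212G>T	p.(Glu1738Ter)	2	.	CM2136516
26	Intron 52	c.7439+1G>T	p.?	2	PM2;PVS1	.
27	1	c.3dup	p.(Pro2AlafsTer48)	1	PM2;PVS1	.
28	1	c.79C>T	p.(Gln27Ter)	1	PM2;PVS1;PP4	.
29	1	c.106C>T	p.(Gln36Ter)	1	PM2;PVS1	.
30	1	del ex 1	p.?	1	.	CG1815550CG1815547
31	2	c.172T>C	p.(Cys58Arg)	1	PM2;PP3;PM3;PP4	CM1724080
32	7	c.958C>T	p.(Gln320Ter)	1	PM2;PVS1;PP4	.
33	12	c.1755del	p.(Ser585ArgfsTer12)	1	.	CD2124491
34	14	c.1894_1895del	p.(Leu632GlufsTer8)	1	PM2;PVS1	.
35	Intron 14	c.2097-1G>A	p.?	1	PM2;PVS1	.
36	15	c.2166A>T	p.(Glu722Asp)	1	PM2;PP3;PM3;PP4	CM2214171
37	16	c.2230C>T	p.(Arg744Ter)	1	.	CM130400CS016102
38	Intron 20	c.2856+2T>A	p.?	1	PM2;PVS1;PM3;PP4	.
39	21	c.2962C>T	p.(Gln988Ter)	1	.	CM981163
40	23	c.3283C>T	p.(Arg1095Ter)	1	.	CM151370
41	25	c.3569del	p.(Ala1190ValfsTer9)	1	PM2;PVS1;PM3;PP4	.
42	25	c.3644del	p.(Pro1215GlnfsTer9)	1	PM2;PVS1	.
43	Intron 25	c.3736-2A>T	p.?	1	.	CS2113419
44	26	c.3799_3821del	p.(Phe1267AspfsTer11)	1	.	CG077478
45	27	c.4048C>T	p.(Arg1350Ter)	1	.	CM102055
46	27	c.4056dup	p.(Arg1353GlnfsTer4)	1	PM2;PVS1;PM3;PP4	.
47	29	C.4198C>T	p.(Arg1400Ter)	1	.	CM1311877
48	29	c.4255_4258dup	p.(Cys1420SerfsTer5)	1	.	CI243376
49	32	c.4645C>T	p.(Arg1549Ter)	1	.	CM001209
50	32	c.4665dup	p. (Lys1556GlufsTer3)	1	PM2;PVS1	.
51	36	c.5188del	p.(Arg1730GlyfsTer4)	1	PM2;PVS1;PM3	.
52	Intron 36	c.5234+1G>A	p.?	1	.	CS085941
53	Intron 36	c.5235-2A>G	p.?	1	PM2;PVS1;PM3;PP4	.
54	37	c.5422C>T	p.(Gln1808Ter)	1	PM2;PVS1;PM3;PP4	.
55	Intron 37	c.5445+1G>A	p.?	1	.	CS206309
56	38	c.5476C>T	p.(Arg1826Ter)	1	.	CM983961
57	Intron 38	c.5562+5G>C	p.?	1	.	CS003701
58	Intron 38	c.5727-2A>G	p.?	1	PM2;PVS1	.
59	39	c.5706del	p.(Ser1903HisfsTer61)	1	PM2;PVS1	.
60	40	del ex 40	p.?	1	PM2;PVS1;PP4	.
61	46	c.6474C>A	p.(Tyr2158Ter)	1	PM2;PVS1;PP4	.
62	46	c.6560delinsTGCCA	p.(Gly2187ValfsTer8)	1	PM2;PVS1;PP4	.
63	48	c.6721G>T	p.(Gly2241Ter)	1	PM2;PVS1;PP4	.
64	Intron 49	c.6993-1G>C	p.?	1	PM2;PVS1;PP4	.
65	50	c.7074C>A	p.(Tyr2358Ter)	1	.	CM981167
66	51	c.7265G>A	p.(Trp2422Ter)	1	PM2;PVS1	.
67	52	c.7377dup	p.(Leu2460SerfsTer2)	1	.	CI020898
68	55	c.7701delTinsGTGTCCCTAGGTGTCCCTA	p.(Ser2567delinsArgCysProTer)	1	PM2;PVS1;PM3;PP4	.
69	56	c.7814del	p.(Thr2605LysfsTer2)	1	PM2;PVS1;PP4	.
70	56	c.7888C>T	p.(Arg2630Ter)	1	.	CM1618984
71	57,58	del ex 57,58	p.?	1	PM2;PVS1;PP4	.
72	58	c.8244+3_8244+6del	p.?	1	.	CD151394
73	61	c.8699_8700insGTAAATTCT	p.(Pro2901Ter)	1	PM2;PVS1;PP4	.
74	64	c.9139G>T	p.(Glu3047Ter)	1	.	CM2320779
75	65	c.9253C>T	p.(Arg3085Ter)	1	.	CM020949
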