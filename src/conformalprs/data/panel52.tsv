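rsid	chrom	pos	ref	alt	risk_allele	odds_ratio	locus	risk_allele_freq
rs187328863	1	196698945	C	T	T	1.47	CFH	0.342
rs114092250	5	35494448	G	A	A	0.71	PRLR/SPEF2	0.36
rs10781182	9	76617720	G	T	T	1.12	MIR6130/RORB	0.436
rs67538026	19	1031438	C	T	T	0.9	CNN2	0.286
rs201459901	20	56653724	T	C	C	0.76	C20orf85	0.237
rs10922109	1	196704632	A	C	C	2.38	CFH	0.41
rs2101001	10	124214448	G	T	T	2.66	ARMS2/HTRA1	0.28
rs9100000	5	233769355	T	A	A	1.198	CFH	0.12
rs9100001	7	131458137	T	G	G	1.165	COL4A3	0.366
rs9100002	10	177522247	C	T	T	1.331	ADAMTS9-AS2	0.299
rs9100003	22	57500780	A	G	G	0.919	COL8A1	0.241
rs9100004	11	57024064	G	A	A	1.169	CFI	0.111
rs9100005	10	92291454	C	G	G	1.104	C9	0.247
rs9100006	4	223446391	G	A	A	1.27	C2/CFB/SKIV2L	0.383
rs9100007	22	109710122	A	C	C	1.193	VEGFA	0.223
rs9100008	14	48384691	C	A	A	1.211	KMT2E/SRPK2	0.15
rs9100009	8	140422112	C	T	T	1.333	PILRB/PILRA	0.381
rs9100010	9	183801668	T	C	C	1.254	TNFRSF10A	0.294
rs9100011	13	23141768	A	T	T	1.311	MIR6130/RORB	0.25
rs9100012	18	179490396	G	C	C	1.255	TRPM3	0.116
rs9100013	15	29434063	T	A	A	1.208	TGFBR1	0.339
rs9100014	9	57474286	G	A	A	1.151	ABCA1	0.157
rs9100015	14	75549465	C	A	A	1.259	ARHGAP21	0.245
rs9100016	19	112909216	G	C	C	1.234	RDH5/CD63	0.211
rs9100017	1	45394346	G	A	A	1.31	ACAD10	0.479
rs9100018	17	86006834	T	C	C	1.271	B3GALTL	0.261
rs9100019	22	17701389	C	T	T	1.159	RAD51B	0.325
rs9100020	6	147147612	G	A	A	0.77	LIPC	0.266
rs9100021	22	230671056	T	C	C	1.246	CETP	0.153
rs9100022	15	154517058	A	T	T	0.889	CTRB2/CTRB1	0.294
rs9100023	18	26368386	G	C	C	1.152	TMEM97/VTN	0.286
rs9100024	7	101545437	G	A	A	0.776	NPLOC4/TSPAN10	0.297
rs9100025	5	64023797	A	G	G	1.108	C3	0.153
rs9100026	12	109480551	C	G	G	1.219	APOE	0.317
rs9100027	7	120137101	T	C	C	0.828	CNN2	0.236
rs9100028	4	39612054	T	A	A	1.174	MMP9	0.478
rs9100029	15	137286372	G	T	T	1.251	SYN3/TIMP3	0.248
rs9100030	14	77712169	A	C	C	1.271	SLC16A8	0.406
rs9100031	16	29927538	G	A	A	1.243	PVRL2	0.35
rs9100032	14	60642495	A	G	G	1.325	CFH	0.362
rs9100033	1	229302873	T	C	C	1.268	COL4A3	0.191
rs9100034	16	102323143	G	A	A	1.305	ADAMTS9-AS2	0.438
rs9100035	9	206006064	A	C	C	1.321	COL8A1	0.298
rs9100036	20	158887197	A	C	C	1.126	CFI	0.218
rs9100037	2	124735807	T	A	A	1.303	C9	0.394
rs9100038	4	86498227	C	G	G	0.91	C2/CFB/SKIV2L	0.213
rs9100039	17	82586655	T	C	C	1.194	VEGFA	0.331
rs9100040	8	116745967	A	C	C	1.237	KMT2E/SRPK2	0.293
rs9100041	18	30908504	G	T	T	1.149	PILRB/PILRA	0.318
rs9100042	1	105219148	T	C	C	1.303	TNFRSF10A	0.249
rs9100043	10	20153710	C	A	A	1.163	MIR6130/RORB	0.46
rs9100044	1	33526819	C	G	G	1.159	TRPM3	0.29
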