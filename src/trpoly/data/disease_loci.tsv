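chrom	start	end	unit	gene	region	mean	median	iqr	q1	q3	mean_len	q1_len	q3_len	disease	omim
chr2	176093058	176093103	GGC	HOXD13	coding	-0.1	0	1.00	-1.00	0.00	45	42	45	Syndactyly, type V	186300
chr4	41745971	41746031	GGC	PHOX2B	coding	0.0	0	2.00	-1.00	1.00	60	57	63	Congenital central hypoventilation syndrome	209880
chr6	45422750	45422801	GGC	RUNX2	coding	-0.7	0	1.00	-1.00	0.00	49	48	51	Cleidocranial dysplasia, forme fruste, with brachydactyly	119600
chr7	27199924	27199966	GGC	HOXA13	coding	0.0	0	2.00	-1.00	1.00	42	39	45	Hand-foot-genital syndrome	140000
chr13	99985448	99985493	GGC	ZIC2	coding	0.1	0	2.00	-1.00	1.00	45	42	48	Holoprosencephaly	609637
chr14	23321472	23321502	GGC	PABPN1	coding	-0.1	0	1.00	-1.00	0.00	30	27	30	Oculopharyngeal muscular dystrophy	164300
chrX	25013649	25013697	GGC	ARX	coding	0.2	0	1.00	0.00	1.00	49	48	51	Early infantile epileptic encephalopathy	308350
chrX	140504316	140504361	GGC	SOX3	coding	0.0	0	2.00	-1.00	1.00	45	42	48	Mental retardation with isolated growth hormone deficiency	300123
chr1	149390802	149390842	GGC	NOTCH2NLC	utr5	6.7	6	5.00	3.00	8.00	60	49	64	Neuronal intranuclear inclusion disease	603472
chr8	104588965	104588999	CCG	LRP12	utr5	0.3	0	2.00	-1.00	1.00	35	31	37	Oculopharyngodistal myopathy	164310
chr10	79826315	79826404	GGC	LOC642361,NUTM2B-AS1	noncoding_exon	2.6	3	3.00	1.00	4.00	97	92	101	Oculopharyngodistal myopathy	618637
chr19	14496042	14496085	CCG	GIPC1	utr5	1.6	0	3.00	-1.00	2.00	48	40	49	Oculopharyngodistal myopathy	618940
chrX	147912050	147912110	GGC	FMR1	utr5	8.7	9	5.00	6.00	11.00	86	78	93	Fragile X syndrome/tremor-ataxia syndrome	300624/300623
chrX	148500637	148500682	GGC	AFF2	utr5	2.2	2	5.00	0.00	5.00	52	45	60	Fragile X syndrome	309548
chr3	63912685	63912715	CAG	ATXN7	coding	0.2	0	2.00	-1.00	1.00	30	27	33	Spinocerebellar ataxia 7	164500
chr4	3074876	3074939	CAG	HTT	coding	-1.2	-2	3.00	-3.00	0.00	59	54	63	Huntington disease	143100
chr6	16327635	16327722	CAG	ATXN1	coding	-1.1	-1	4.00	-3.00	1.00	84	78	90	Spinocerebellar ataxia 1	164400
chr6	170561907	170562021	CAG	TBP	coding	-2.7	-3	3.00	-4.00	-1.00	106	102	111	Spinocerebellar ataxia 17	607136
chr12	6936716	6936773	CAG	ATN1	coding	-2.5	-2	5.00	-5.00	0.00	49	42	57	Dentatorubral-pallidoluysian atrophy	125370
chr12	111598950	111599019	CAG	ATXN2	coding	-1.4	-1	1.00	-2.00	-1.00	65	63	66	Spinocerebellar ataxia 2	183090
chr14	92071010	92071040	CAG	ATXN3	coding	7.2	8	10.00	1.00	11.00	51	33	63	Spinocerebellar ataxia 3	109150
chr19	13207858	13207897	CAG	CACNA1A	coding	-2.0	-2	2.00	-3.00	-1.00	33	30	36	Spinocerebellar ataxia 6	183086
chrX	67545317	67545386	CAG	AR	coding	-1.7	-2	5.00	-4.00	1.00	64	57	72	Spinal and bulbar muscular atrophy	313200
chr2	190880868	190880920	GCA	GLS	utr5	-4.3	-3	6.75	-8.00	-1.25	39	28	48	Global developmental delay, progressive ataxia, and elevated glutamine	618412
chr18	55586153	55586229	AGC	TCF4	utr5	-5.5	-7	9.00	-10.00	-1.00	59	46	73	Fuchs corneal dystrophy	602272
chr19	45770204	45770264	CAG	DMPK	utr3	-9.4	-9	5.00	-12.00	-7.00	32	24	39	Myotonic dystrophy 1	160900
chr2	96197066	96197124	AAAAT	STARD7	intron	2.9	1	3.00	0.00	3.00	72	58	73	Myoclonic epilepsy	607876
chr3	183712187	183712226	TTTTA	YEATS2	intron	11.0	2	30.00	0.00	30.00	94	39	189	Myoclonic epilepsy	615127
chr4	159342526	159342618	AAAAT	RAPGEF2	intron	0.5	1	1.00	0.00	1.00	94	92	97	Epilepsy, familial adult myoclonic, 7	618075
chr5	10356339	10356411	AAAAT	MARCHF6	intron	0.4	0	1.00	0.00	1.00	74	72	77	Myoclonic epilepsy	613608
chr8	118366815	118366918	AAAAT	SAMD12	intron	-0.8	-1	3.00	-2.00	1.00	99	93	108	Epilepsy, familial adult myoclonic, 1	601068
chr16	24613438	24613532	AAAAT	TNRC6A	intron	-5.0	-5	2.00	-6.00	-4.00	69	64	74	Epilepsy, familial adult myoclonic, 6	618074
chr16	66490396	66490466	AAAAT	BEAN1	intron	24.1	3	7.00	-1.00	6.00	190	65	100	Spinocerebellar ataxia 31	117210
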