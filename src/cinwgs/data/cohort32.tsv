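sample_id	age	pathology	size_class	er	pr	her2	ki67	vascular_invasion	brca1_cdna	brca1_protein	tp53_status	cin_category
BRCA1-01	47	IDC	2	+	+	-	30%	Y	c.1209delT	p.Glu404AsnfsTer6	LOSS	High
BRCA1-03	40	IDC	1	-	-	-	NA	N	c.3295delC	p.Pro1099LeufsTer10	WT	Low
BRCA1-04	57	DCIS	1	+	-	+	30%	N	c.5251C>T	p.Arg1751Ter	LOSS	High
BRCA1-05	40	IDC	1	-	-	-	NA	N	c.5154G>A	p.Trp1718Ter	WT	Low
BRCA1-08	44	IDC	1	-	-	-	20%	N	c.223G>T	p.Glu75Ter	WT	Low
BRCA1-09	46	IDC	2	-	-	-	60%	N	c.4228delG	p.Glu1410LysfsTer5	LOSS	High
BRCA1-13	45	IDC	2	-	-	-	40%	N	c.5362delT	p.Gly1788ValfsTer5	LOSS	High
BRCA1-15	49	IDC	1	-	-	-	60%	N	c.5521delT	p.Ser1841ValfsTer2	WT	High
BRCA1-20	46	DCIS	1	+	-	-	10%	N	c.5137G>A	p.Asp1713Asn	WT	Low
BRCA1-32	50	IDC	2	-	-	-	45%	N	c.2971_2975delAAAAC	p.Lys991Ter	WT	Low
BRCA1-23	49	IDC	1	-	-	-	80%	N	c.4065_4068delTCAA	p.Asn1355LysfsTer10	WT	Low
BRCA1-37	37	IDC	2	-	-	-	20%	N	c.302-2A>C	NA	WT	Low
BRCA1-38	33	IDC	2	+	-	-	70%	N	Exon13-14dup	NA	WT	Low
BRCA1-26	54	IDC	2	-	-	-	NA	N	c.140G>T	p.Cys47Phe	WT	Low
BRCA1-30	29	IDC	1	-	-	-	70%	N	c.5470_5477delATTGGGCA	p.Ile1824AspfsTer3	WT	Low
BRCA1-18	44	DCIS	2	-	-	-	10%	N	c.981_982delAT	p.Cys328Ter	WT	Low
BRCA1-34	32	IDC	2	-	-	-	NA	Y	c.5161C>T	p.Gln1721Ter	LOSS	Low
BRCA1-33	40	IDC	2	+	+	-	15%	Y	c.4063_4066delAATC	p.Asn1355LysfsTer10	LOSS	Low
BRCA1-36	38	IDC	2	-	-	-	90%	Y	c.5468-1_5474delGCAATTGG	NA	WT	Low
BRCA1-22	50	IDC	1	+	+	-	40%	N	c.4228delC	p.Glu1410LysfsTer5	WT	Low
BRCA1-24	55	IDC	2	-	-	-	NA	N	c.2110_2111delAA	p.Asn704CysfsTer7	WT	Low
BRCA1-16	52	IDC	2	-	-	-	85%	N	c.5470_5477delATTGGGCA	p.Ile1824AspfsTer3	LOSS	High
BRCA1-35	36	IDC	2	-	+	-	90%	N	c.4453_4454delAC	p.Thr1485GlnfsTer2	WT	Low
BRCA1-31	39	IDC	NA	NA	NA	NA	NA	N	c.3780delAG	p.Leu1260PhefsTer6	LOSS	Low
BRCA1-19	42	IDC	1	-	-	-	35%	N	Exon5-7dup	NA	LOSS	High
BRCA1-27	58	IDC	1	-	-	-	NA	N	c.1465G>T	p.Glu489Ter	LOSS	High
BRCA1-29	47	IDC	3	+	-	-	0.6	Y	c.3770_3771delAG	p.Glu1257GlyfsTer9	LOSS	High
BRCA1-12	35	IDC	3	-	-	-	80%	N	c.4864A>T	p.Lys1622Ter	LOSS	High
BRCA1-07	48	IDC	1	-	-	-	70%	N	c.1058G>A	p.Trp353Ter	WT	High
BRCA1-11	39	IDC	1	-	-	-	70%	Y	c.4564delT	p.Tyr1522ThrfsTer26	LOSS	High
BRCA1-25	40	IDC	1	-	-	-	80%	Y	c.5137G>A	p.Asp1713Asn	LOSS	High
BRCA1-14	20	IDC	1	-	-	-	80%	N	c.537C>A	p.Tyr179Ter	LOSS	High
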