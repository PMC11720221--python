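accession	start	end	seg_class	description
O00481	255	271	tm_helix	transmembrane helix
O43613	120	140	tm_helix	transmembrane helix
P00395	447	478	tm_helix	transmembrane helix
P04233	47	72	tm_helix	transmembrane helix
P16260	191	211	tm_helix	transmembrane helix
P21796	202	211	tm_strand	transmembrane beta strand
P21796	231	238	tm_strand	transmembrane beta strand
P46977	120	138	tm_helix	transmembrane helix
P51677	240	264	tm_helix	transmembrane helix
Q02094	333	353	tm_helix	transmembrane helix flanking annotated domain
Q02094	354	362	non_tm	extracellular
Q02094	363	383	tm_helix	transmembrane helix
Q03518	54	76	tm_helix	transmembrane helix
Q08AI6	121	141	tm_helix	transmembrane helix
Q13635	101	121	tm_helix	transmembrane helix
Q13635	437	457	tm_helix	transmembrane helix
Q15413	4187	4207	tm_helix	transmembrane helix
Q5H9E4	181	201	tm_helix	transmembrane helix
Q6ZXV5	318	338	tm_helix	transmembrane helix
Q86UQ4	4536	4556	tm_helix	transmembrane helix
Q8IZY2	550	570	tm_helix	transmembrane helix
Q8N4F7	104	121	tm_helix	transmembrane helix
Q8NGY3	116	136	tm_helix	transmembrane helix
Q8TCQ1	155	175	tm_helix	transmembrane helix
Q96FL9	7	26	tm_helix	transmembrane helix
Q9H9B4	229	249	tm_helix	transmembrane helix
Q9NX47	238	258	tm_helix	transmembrane helix
Q9Y277	69	76	tm_strand	transmembrane beta strand
O00299	26	46	tm_helix	transmembrane helix (after insertion into the membrane)
P04839	103	123	tm_helix	transmembrane helix
P35499	1160	1179	tm_helix	transmembrane helix
Q2M385	233	247	tm_helix	transmembrane element carrying the predicted site (see notes)
Q2M385	248	256	tm_strand	transmembrane beta strand
Q6P4E1	15	35	tm_helix	transmembrane helix
P49788	21	42	tm_helix	transmembrane helix
P11279	29	382	non_tm	lumenal
P11279	383	403	tm_helix	transmembrane helix flanking annotated domain
P48145	62	72	non_tm	cytoplasmic
P48145	73	93	tm_helix	transmembrane helix flanking annotated domain
P35670	765	785	tm_helix	transmembrane helix
P35670	786	919	non_tm	cytoplasmic
P23634	995	1015	tm_helix	transmembrane helix flanking annotated domain
P23634	1016	1025	non_tm	extracellular
P23634	1026	1046	tm_helix	transmembrane helix flanking annotated domain
O43292	496	516	tm_helix	transmembrane helix flanking annotated domain
O43292	517	543	non_tm	lumenal
Q9Y5Y9	1291	1311	tm_helix	transmembrane helix flanking annotated domain
Q9Y5Y9	1312	1353	non_tm	extracellular
Q15878	1561	1571	non_tm	extracellular
Q15878	1572	1592	tm_helix	transmembrane helix flanking annotated domain
Q14165	29	269	non_tm	lumenal
Q14165	270	290	tm_helix	transmembrane helix flanking annotated domain
Q00975	1556	1563	non_tm	extracellular
Q00975	1564	1584	tm_helix	transmembrane helix flanking annotated domain
Q8NA29	222	241	non_tm	extracellular
Q8NA29	242	262	tm_helix	transmembrane helix flanking annotated domain
Q08722	198	207	non_tm	extracellular
Q08722	208	228	tm_helix	transmembrane helix flanking annotated domain
Q9H1C4	428	448	tm_helix	transmembrane helix
Q9H1C4	449	468	non_tm	not annotated in Uniprot
O00206	24	631	non_tm	extracellular
O00206	632	652	tm_helix	transmembrane helix flanking annotated domain
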