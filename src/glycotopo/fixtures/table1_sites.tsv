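accession	position	residue	glycan_class	status	evidence	domain_start	domain_end	domain_description	structure	glycan_in_structure	protein_name
O00481	255	T	O-GlcNAc	reported	29351928	255	271	transmembrane	-		Butyrophilin subfamily 3 member A1
O43613	129	S	O-GlcNAc	reported	29351928	120	140	transmembrane	6TO7		Orexin/Hypocretin receptor type 1
O43613	138	S	O-GlcNAc	reported	29351928	120	140	transmembrane	6TO7		Orexin/Hypocretin receptor type 1
P00395	455	S	O-GlcNAc	reported	28510447;29351928	447	478	transmembrane	5Z62		Cytochrome c oxidase subunit 1
P04233	66	T	O-GlcNAc	reported	29351928	47	72	transmembrane	-		HLA class II histocompatibility antigen gamma chain
P16260	195	T	O-GlcNAc	reported	29351928	191	211	transmembrane	AF-P16260-F1-v4		Solute carrier family 25 member 16
P16260	206	S	O-GlcNAc	reported	29351928	191	211	transmembrane	AF-P16260-F1-v4		Solute carrier family 25 member 16
P21796	211	T	O-GlcNAc	reported	33214551;30397120;34725712;23576270;32119511;28657654	202	211	transmembrane	5XDN		Non-selective voltage-gated ion channel VDAC1
P46977	124	S	O-GlcNAc	reported	34846842;34725712;30059200;29351928;34019948;35083852;32119511;35254053	120	138	transmembrane	6S7O		Dolichyl-diphosphooligosaccharide-protein glycosyltransferase subunit STT3A
P51677	253	T	O-GlcNAc	reported	29351928	240	264	transmembrane	7X9Y		C-C chemokine receptor type 3
P51677	262	S	O-GlcNAc	reported	29351928	240	264	transmembrane	7X9Y		C-C chemokine receptor type 3
Q02094	371	T	O-GlcNAc	reported	29351928	363	383	transmembrane	8CSX		Ammonium transporter Rh type A
Q03518	63	S	O-GlcNAc	reported	27655845;30379171;28510447	54	76	transmembrane	-		Antigen peptide transporter 1
Q08AI6	125	S	O-GlcNAc	reported	29351928	121	141	transmembrane	AF-Q08AI6-F1-v4		Putative sodium-coupled neutral amino acid transporter 11
Q08AI6	128	S	O-GlcNAc	reported	29351928	121	141	transmembrane	AF-Q08AI6-F1-v4		Putative sodium-coupled neutral amino acid transporter 11
Q13635	444	S	O-GlcNAc	reported	30379171;38253038	437	457	transmembrane	6DMB		Protein patched homolog 1
Q15413	4201	T	O-GlcNAc	reported	29351928;30620550;37217939;38253038;35254053	4187	4207	transmembrane	-		Ryanodine receptor 3
Q5H9E4	194	S	O-GlcNAc	reported	30620550	181	201	transmembrane	AF-Q5H9E4-F1-v4		Solute carrier family 25 member 53
Q6ZXV5	337	S	O-GlcNAc	reported	34725712;38665916;29351928	318	338	transmembrane	AF-Q6ZXV5-F1-v4		Protein O-mannosyl-transferase TMTC3
Q86UQ4	4539	T	O-GlcNAc	reported	37217939;29351928	4536	4556	transmembrane	-		ATP-binding cassette sub-family A member 13
Q86UQ4	4544	S	O-GlcNAc	reported	37217939;29351928	4536	4556	transmembrane	-		ATP-binding cassette sub-family A member 13
Q86UQ4	4550	T	O-GlcNAc	reported	37217939;29351928	4536	4556	transmembrane	-		ATP-binding cassette sub-family A member 13
Q8IZY2	555	T	O-GlcNAc	reported	35008409;29351928	550	570	transmembrane	8EDW		Phospholipid-transporting ATPase ABCA7
Q8N4F7	107	S	O-GlcNAc	reported	29351928	104	121	transmembrane	AF-Q8N4F7-F1-v4		RING finger protein 175
Q8NGY3	132	T	O-GlcNAc	reported	29351928	116	136	transmembrane	AF-Q8NGY3-F1-v4		Olfactory receptor 6K3
Q8NGY3	133	T	O-GlcNAc	reported	29351928	116	136	transmembrane	AF-Q8NGY3-F1-v4		Olfactory receptor 6K3
Q8TCQ1	158	S	O-GlcNAc	reported	29351928	155	175	transmembrane	-		E3 ubiquitin-protein ligase MARCHF1
Q8TCQ1	160	T	O-GlcNAc	reported	29351928	155	175	transmembrane	-		E3 ubiquitin-protein ligase MARCHF1
Q96FL9	19	T	O-GlcNAc	reported	29351928	7	26	transmembrane	-		Polypeptide N-acetylgalactosaminyltransferase 14
Q9H9B4	232	S	O-GlcNAc	reported	38665916;34725712;37217939;35083852;36240223;33465208	229	249	transmembrane	AF-Q9H9B4-F1-v4		Sideroflexin-1
Q9NX47	238	T	O-GlcNAc	reported	30379171	238	258	transmembrane	-		E3 ubiquitin-protein ligase MARCHF5
Q9Y277	70	T	O-GlcNAc	reported	27655845;23301498;38665916;34725712;35132862;35083852;32870666;34931806;32119511	69	76	transmembrane	AF-Q9Y277-F1-v4		Voltage-dependent anion-selective channel protein 3
O00299	42	N	N-linked	reported	23090970;24190977	26	46	transmembrane	1RK4		Chloride intracellular channel protein 1
P04839	122	N	N-linked	reported	24190977	103	123	transmembrane	8GZ3		Cytochrome b-245 heavy chain
P35499	1162	N	N-linked	reported	PDB annotations for 6AGF	1160	1179	transmembrane	6AGF		Sodium channel protein type 4 subunit alpha
P21796	238	N	N-linked	reported	37074911	231	238	transmembrane	5XDN		Non-selective voltage-gated ion channel VDAC1
Q2M385	255	N	N-linked	reported	37074911;24190977	248	256	transmembrane	6U2J		Macrophage-expressed gene 1 protein
Q6P4E1	31	N	N-linked	reported	24190977	15	35	transmembrane	-		Protein GOLM2
Q13635	120	N	N-linked	reported	PDB annotations for 6DMB;6DMO;6DMY	101	121	transmembrane	6DMB		Protein patched homolog 1
P49788	40	S	O-linked-other	predicted	27399812;36213313;37453717	21	42	transmembrane	-		Retinoic acid receptor responder protein 1
Q2M385	237	T	unreported	predicted	GlyGen dataset GLY_001151				6U2J		Macrophage-expressed gene 1 protein
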