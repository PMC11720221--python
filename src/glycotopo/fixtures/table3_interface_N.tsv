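accession	position	residue	glycan_class	status	evidence	domain_start	domain_end	domain_description	structure	glycan_in_structure	protein_name
O43292	517	N	N-linked	predicted		517	543	lumenal	7W72;7WLD;8IMX;8IMY	no	Glycosylphosphatidylinositol anchor attachment 1 protein
Q9Y5Y9	1312	N	N-linked	predicted		1312	1353	extracellular	7WFR;7WEL;7WE4;7WFW	yes	Sodium channel protein type 10 subunit alpha
Q15878	1571	N	N-linked	predicted		1561	1571	extracellular	7XLQ;7YG5;8EPL;8EPM	no	Voltage-dependent R-type calcium channel subunit alpha-1E
Q02094	355	N	N-linked	predicted		354	362	extracellular	7UZQ;7V0K;7V0S;8CRT;8CS9;8CSX;8CTE	no	Ammonium transporter Rh type A
Q14165	268	N	N-linked	predicted		29	269	lumenal	6S7T	no	Malectin
Q00975	1563	N	N-linked	predicted		1556	1563	extracellular	7VFU;7VFV;7VFW;7VFS;7MIX;7MIY	no	Voltage-dependent N-type calcium channel subunit alpha-1B
Q8NA29	240	N	N-linked	predicted		222	241	extracellular	7OIX	no	Sodium-dependent lysophosphatidylcholine symporter 1
Q08722	206	N	N-linked	predicted		198	207	extracellular	7MYZ	no	Leukocyte surface antigen CD47
Q9H1C4	449	N	N-linked	predicted		449	468	not annotated in Uniprot	7CYN;7C76;7C77	no	Protein unc-93 homolog B1
O00206	630	N	N-linked	predicted		24	631	extracellular	5NAM;5NAO	no	Toll-like receptor 4
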