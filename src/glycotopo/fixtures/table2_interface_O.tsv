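accession	position	residue	glycan_class	status	evidence	domain_start	domain_end	domain_description	structure	glycan_in_structure	protein_name
P11279	381	S	O-GlcNAc	reported	23301498;33214551;8665916;26374642;34725712;29351928;34019948;33465208;35289036;32119511;36240223;28657654	29	382	lumenal	AF-P11279-F1		Lysosome-associated membrane glycoprotein 1
P48145	70	T	O-GlcNAc	reported	29351928	62	72	cytoplasmic	AF-P48145-F1		Neuropeptides B/W receptor type 1
P35670	788	T	O-GlcNAc	reported	30379171;29351928	786	919	cytoplasmic	7XUK;7XUM;7XUN;7XUO;8IOY		Copper-transporting ATPase 2
P23634	1051	T	O-GlcNAc	reported	28510447;33465208;38665916;29351928	1016	1025	extracellular	AF-P23634-F1		Plasma membrane calcium-transporting ATPase 4
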