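profile	component	value
amino_acids	ala	10.0
amino_acids	arg	5.0
amino_acids	asx	9.5
amino_acids	cys	0.6
amino_acids	glx	10.5
amino_acids	gly	8.6
amino_acids	his	2.0
amino_acids	ile	6.0
amino_acids	leu	8.5
amino_acids	lys	7.0
amino_acids	met	1.4
amino_acids	phe	4.0
amino_acids	pro	4.5
amino_acids	ser	5.8
amino_acids	thr	5.6
amino_acids	trp	1.0
amino_acids	tyr	3.0
amino_acids	val	7.0
rna_bases	amp	25.8
rna_bases	cmp	19.5
rna_bases	gmp	28.5
rna_bases	ump	26.2
lipid_glycerol	tag	30.0
lipid_glycerol	ffa	12.0
lipid_glycerol	ste	16.0
lipid_glycerol	car	4.0
lipid_glycerol	pa	8.0
lipid_glycerol	pc	16.0
lipid_glycerol	pi_ps	14.0
lipid_methanol	tag	2.0
lipid_methanol	ffa	50.0
lipid_methanol	ste	16.0
lipid_methanol	car	4.0
lipid_methanol	pa	2.0
lipid_methanol	pc	14.0
lipid_methanol	pi_ps	12.0
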