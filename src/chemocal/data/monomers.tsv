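class	id	formula	polymerizes
protein	ala	C3H7NO2	1
protein	arg	C6H14N4O2	1
protein	asn	C4H8N2O3	1
protein	asp	C4H7NO4	1
protein	cys	C3H7NO2S	1
protein	gln	C5H10N2O3	1
protein	glu	C5H9NO4	1
protein	gly	C2H5NO2	1
protein	his	C6H9N3O2	1
protein	ile	C6H13NO2	1
protein	leu	C6H13NO2	1
protein	lys	C6H14N2O2	1
protein	met	C5H11NO2S	1
protein	phe	C9H11NO2	1
protein	pro	C5H9NO2	1
protein	ser	C3H7NO3	1
protein	thr	C4H9NO3	1
protein	trp	C11H12N2O2	1
protein	tyr	C9H11NO3	1
protein	val	C5H11NO2	1
rna	amp	C10H14N5O7P	1
rna	gmp	C10H14N5O8P	1
rna	cmp	C9H14N3O8P	1
rna	ump	C9H13N2O9P	1
dna	damp	C10H14N5O6P	1
dna	dgmp	C10H14N5O7P	1
dna	dcmp	C9H14N3O7P	1
dna	dtmp	C10H15N2O8P	1
carbohydrate	glucose	C6H12O6	1
lipid	tag	C57H104O6	0
lipid	ffa	C18H34O2	0
lipid	ste	C28H44O	0
lipid	car	C81H142O17P2	0
lipid	pa	C39H73O8P	0
lipid	pc	C44H84NO8P	0
lipid	pi	C47H87O13P	0
lipid	ps	C42H78NO10P	0
so4	so4	O4S	0
h2o	h2o	H2O	0
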