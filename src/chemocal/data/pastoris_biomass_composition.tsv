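substrate	condition	component	value	sd
glycerol	0.035	protein	36.0	6.7
glycerol	0.065	protein	41.2	0.4
glycerol	0.100	protein	41.1	2.9
glycerol	0.160	protein	43.3	2.8
methanol	0.035	protein	48.6	1.0
methanol	0.065	protein	50.7	0.5
methanol	0.100	protein	51.5	2.1
glycerol	average	protein	41.0	1.5
methanol	average	protein	50.1	0.8
glucose	average	protein	37.0	2.4
glycerol	0.035	carbohydrate	45.6	7.5
glycerol	0.065	carbohydrate	37.0	1.1
glycerol	0.100	carbohydrate	35.9	3.1
glycerol	0.160	carbohydrate	33.9	1.3
methanol	0.035	carbohydrate	29.0	2.8
methanol	0.065	carbohydrate	28.9	0.8
methanol	0.100	carbohydrate	23.5	1.3
glycerol	average	carbohydrate	35.9	2.0
methanol	average	carbohydrate	27.3	1.5
glucose	average	carbohydrate	36.9	3.5
glycerol	0.035	lipid	1.3	0.3
glycerol	0.065	lipid	1.8	0.4
glycerol	0.100	lipid	2.2	0.5
glycerol	0.160	lipid	2.8	0.03
methanol	0.035	lipid	2.2	0.2
methanol	0.065	lipid	1.9	0.1
methanol	0.100	lipid	2.4	0.6
glycerol	average	lipid	2.5	0.4
methanol	average	lipid	2.0	0.2
glucose	average	lipid	6.2	3.3
glycerol	0.035	rna	6.0	0.1
glycerol	0.065	rna	6.7	1.1
glycerol	0.100	rna	7.6	1.2
glycerol	0.160	rna	9.1	2.6
methanol	0.035	rna	5.7	0.6
methanol	0.065	rna	6.3	1.3
methanol	0.100	rna	7.1	0.4
glycerol	average	rna	7.8	0.6
methanol	average	rna	7.0	0.6
glucose	average	rna	6.6	0.7
glycerol	0.035	dna	0.19	0.001
glycerol	0.065	dna	0.19	0.01
glycerol	0.100	dna	0.18	0.01
glycerol	0.160	dna	0.18	0.01
methanol	0.035	dna	0.19	0.004
methanol	0.065	dna	0.18	0.004
methanol	0.100	dna	0.18	0.02
glycerol	average	dna	0.19	0.01
methanol	average	dna	0.18	0.01
glucose	average	dna	0.13	0.01
glycerol	0.035	so4	0.28	0.06
glycerol	0.065	so4	0.40	0.001
glycerol	0.100	so4	0.45	0.10
glycerol	0.160	so4	0.46	0.11
methanol	0.035	so4	0.63	0.004
methanol	0.065	so4	0.69	0.05
methanol	0.100	so4	0.66	0.06
glycerol	average	so4	0.46	0.08
methanol	average	so4	0.63	0.04
glucose	average	so4	0.3	0.3
glycerol	0.035	h2o	5.8	0.6
glycerol	0.065	h2o	5.7	0.2
glycerol	0.100	h2o	6.6	2.5
glycerol	0.160	h2o	6.6	0.2
methanol	0.035	h2o	8.4	0.1
methanol	0.065	h2o	6.2	1.8
methanol	0.100	h2o	8.1	0.7
glycerol	average	h2o	5.6	0.7
methanol	average	h2o	7.2	0.9
glucose	average	h2o	6.3	2.4
glycerol	0.035	metals	5.3	1.0
glycerol	0.065	metals	7.0	0.1
glycerol	0.100	metals	6.0	0.9
glycerol	0.160	metals	5.8	1.1
methanol	0.035	metals	5.3	2.1
methanol	0.065	metals	5.2	2.0
methanol	0.100	metals	6.6	0.1
glycerol	average	metals	7.0	0.6
methanol	average	metals	6.3	0.6
glucose	average	metals	6.4	0.4
glycerol	0.035	C	42.3	0.1
glycerol	0.065	C	41.9	0.1
glycerol	0.100	C	41.9	0.9
glycerol	0.160	C	42.44	1.00
methanol	0.035	C	42.2	0.8
methanol	0.065	C	43.2	0.1
methanol	0.100	C	41.8	0.2
glycerol	average	C	41.98	0.27
methanol	average	C	42.28	0.53
glucose	average	C	43.0	1.4
glycerol	0.035	H	6.3	0.03
glycerol	0.065	H	6.24	0.002
glycerol	0.100	H	6.3	0.2
glycerol	0.160	H	6.44	0.08
methanol	0.035	H	6.6	0.1
methanol	0.065	H	6.5	0.2
methanol	0.100	H	6.5	0.1
glycerol	average	H	6.24	0.06
methanol	average	H	6.43	0.05
glucose	average	H	6.3	0.2
glycerol	0.035	N	7.4	1.2
glycerol	0.065	N	8.4	0.1
glycerol	0.100	N	8.7	0.7
glycerol	0.160	N	9.22	0.24
methanol	0.035	N	9.7	0.1
methanol	0.065	N	10.2	0.1
methanol	0.100	N	10.4	0.4
glycerol	average	N	8.58	0.31
methanol	average	N	10.06	0.16
glucose	average	N	6.9	0.4
glycerol	0.035	O	37.8	2.2
glycerol	0.065	O	35.4	0.04
glycerol	0.100	O	36.0	2.6
glycerol	0.160	O	34.98	0.40
methanol	0.035	O	35.2	1.3
methanol	0.065	O	33.9	1.6
methanol	0.100	O	33.4	0.7
glycerol	average	O	35.11	0.58
methanol	average	O	33.83	0.46
glucose	average	O	36.4	1.4
glycerol	0.035	S	0.25	0.06
glycerol	0.065	S	0.30	0.001
glycerol	0.100	S	0.25	0.04
glycerol	0.160	S	0.30	0.04
methanol	0.035	S	0.41	0.01
methanol	0.065	S	0.4	0.02
methanol	0.100	S	0.43	0.03
glycerol	average	S	0.30	0.03
methanol	average	S	0.41	0.01
glucose	average	S	0.2	0.1
glycerol	0.035	ash	5.9	1.0
glycerol	0.065	ash	7.7	0.004
glycerol	0.100	ash	6.8	1.1
glycerol	0.160	ash	6.6	1.3
methanol	0.035	ash	5.9	2.0
methanol	0.065	ash	5.9	1.8
methanol	0.100	ash	7.4	0.1
glycerol	average	ash	7.8	0.6
methanol	average	ash	7.0	0.6
glucose	average	ash	7.1	0.4
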