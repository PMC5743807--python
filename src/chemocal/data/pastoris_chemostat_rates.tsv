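substrate	D_set	mu	mu_sd	q_S	q_S_sd	q_O2	q_O2_sd	q_CO2	q_CO2_sd	q_X	q_X_sd	Y_XS	Y_XS_sd	RQ	RQ_sd
glycerol	0.035	0.035	0.001	-0.58	0.05	-0.82	0.13	0.53	0.11	1.22	0.04	0.65	0.03	0.64	0.03
glycerol	0.050	0.049	0.002	-0.85	0.06	-1.26	0.10	0.84	0.08	1.70	0.14	0.62	0.05	0.67	0.07
glycerol	0.065	0.064	0.0005	-1.07	0.01	-1.52	0.02	1.00	0.02	2.22	0.02	0.64	0.0005	0.65	0.0005
glycerol	0.100	0.094	0.004	-1.52	0.08	-2.04	0.11	1.28	0.08	3.27	0.15	0.71	0.04	0.63	0.01
glycerol	0.130	0.124	0.001	-1.92	0.08	-2.36	0.15	1.41	0.13	4.36	0.24	0.71	0.04	0.60	0.07
glycerol	0.160	0.154	0.002	-2.41	0.03	-2.92	0.01	1.74	0.001	5.47	0.08	0.70	0.002	0.60	0.003
methanol	0.035	0.035	0.001	-2.81	0.16	-2.98	0.22	1.59	0.14	1.22	0.02	0.38	0.01	0.53	0.01
methanol	0.050	0.049	0.0002	-3.88	0.10	-4.07	0.15	2.15	0.10	1.73	0.01	0.39	0.01	0.53	0.01
methanol	0.065	0.065	0.001	-4.87	0.22	-4.97	0.29	2.55	0.18	2.33	0.04	0.41	0.01	0.51	0.01
methanol	0.080	0.084	0.001	-6.23	0.16	-6.36	0.18	3.27	0.12	2.96	0.13	0.42	0.02	0.51	0.02
methanol	0.100	0.099	0.001	-7.82	0.28	-8.22	0.37	4.34	0.24	3.47	0.04	0.40	0.01	0.53	0.01
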