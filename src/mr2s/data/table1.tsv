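rsid	chr	gene	effect_allele	other_allele	eaf	beta	se	pvalue	or	ci_low	ci_high	pvalue_outcome	study	proxy_rsid
rs12498742	4	SLC2A9	A	G	0.77	0.373	0.006	1e-300	1.00	0.96	1.04	0.961	IMSGC	rs7442295
rs2231142	4	ABCG2	T	G	0.11	0.217	0.009	1.0e-134	0.99	0.94	1.05	0.795	IMSGC
rs1260326	2	GCKR	T	C	0.41	0.074	0.005	1.2e-44	1.00	0.96	1.03	0.749	IMSGC
rs3741414	12	INHBC	T	C	0.24	-0.072	0.007	2.2e-25	1.01	0.97	1.05	0.678	IMSGC
rs675209	6	RREB1	T	C	0.27	0.061	0.006	1.3e-23	1.04	1.00	1.08	0.048	IMSGC
rs11264341	1	TRIM46	T	C	0.43	-0.050	0.006	6.2e-19	1.03	0.99	1.06	0.109	IMSGC
rs653178	12	ATXN2	T	C	0.51	-0.035	0.005	7.2e-12	0.95	0.92	0.98	0.002	IMSGC
rs1178977	7	BAZ1B	A	G	0.81	0.047	0.007	1.2e-12	0.97	0.93	1.01	0.171	IMSGC	rs17145713
rs10480300	7	PRKAG2	T	C	0.28	0.035	0.006	4.1e-09	1.02	0.99	1.06	0.267	IMSGC	rs10224002
rs1165151	6	SLC17A1	T	G	0.47	-0.091	0.005	7.0e-70	0.94	0.91	0.97	3.8e-4	WTCCC2	rs9393672
rs2078267	11	SLC22A11	T	C	0.51	-0.073	0.006	9.4e-38	0.97	0.94	1.00	0.082	WTCCC2
rs7224610	17	HLF	A	C	0.58	-0.042	0.005	5.4e-17	1.02	0.99	1.06	0.241	WTCCC2
rs6598541	15	IGF1R	A	G	0.36	0.043	0.006	4.8e-15	0.99	0.95	1.03	0.606	WTCCC2	rs3743264
rs1394125	15	UBE2Q2	A	G	0.34	0.043	0.006	2.5e-13	0.97	0.93	1.01	0.106	WTCCC2
rs7193778	16	NFAT5	T	C	0.86	-0.046	0.008	8.2e-10	1.02	0.97	1.07	0.488	WTCCC2	rs33063
rs17050272	2	INHBB	A	G	0.43	0.035	0.006	1.6e-10	1.01	0.97	1.04	0.718	WTCCC2	rs6706968
rs7188445	16	MAF	A	G	0.33	-0.032	0.005	1.6e-09	0.97	0.93	1.01	0.160	WTCCC2	rs17767383
rs17786744	8	STC1	A	G	0.58	-0.029	0.005	1.4e-08	1.00	0.96	1.04	0.900	WTCCC2	rs1705699
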