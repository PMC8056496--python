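rsid	gene	major	minor	gwas_or	in_prs	ref_maf_controls	ref_n_controls	ref_maf_african	ref_n_african	ref_maf_european	ref_n_european	ref_maf_asian	ref_n_asian
rs11655237	LINC00673	C	T	1.06	true	0.13	256	NA	NA	NA	NA	NA	NA
rs2736098	TERT	G	A	0.79	true	0.25	256	NA	NA	NA	NA	NA	NA
rs351365	WNT2B	G	A	0.85	true	0.29	256	NA	NA	NA	NA	NA	NA
rs3790844	NR5A2	T	C	0.61	true	0.27	256	0.13	6740	0.23	158742	0.66	414
rs1486134	ETAA1	T	G	1.03	true	0.25	256	NA	NA	NA	NA	NA	NA
rs16986825	ZNRF3	C	T	0.76	true	0.17	256	NA	NA	NA	NA	NA	NA
rs17688601	SUGCT	C	A	0.63	true	0.25	256	0.07	2012	0.26	119368	0.05	280
rs9581943	PDX1	G	A	1.22	true	0.36	256	NA	NA	NA	NA	NA	NA
rs35226131	PDX1	C	T	1.0	true	0.0	256	NA	NA	NA	NA	NA	NA
rs1561927	MIR1208	T	C	1.47	true	0.24	256	NA	NA	NA	NA	NA	NA
rs9854771	TP63	G	A	0.53	true	0.39	256	0.28	3086	0.36	93526	0.14	238
rs73328514	TNS3	A	T	1.56	true	0.10	256	NA	NA	NA	NA	NA	NA
rs7310409	HNF1A	G	A	1.41	true	0.41	256	0.32	6064	0.40	153574	0.38	370
rs1517037	GRP	C	T	1.18	true	0.21	256	NA	NA	NA	NA	NA	NA
rs2853677	TERT	A	G	0.70	true	0.46	256	NA	NA	NA	NA	NA	NA
rs2941471	HNF4G	A	G	0.64	true	0.44	256	0.13	82	0.42	2072	0.50	4
rs6971499	LINC-PINT	A	G	1.24	true	0.11	256	NA	NA	NA	NA	NA	NA
rs10991043	SMC2	T	C	1.10	true	0.39	256	NA	NA	NA	NA	NA	NA
rs401681	CLPTM1L	C	T	1.53	true	0.45	256	NA	NA	NA	NA	NA	NA
rs13303010	NOC2L	A	G	1.88	true	0.22	256	0.64	3306	0.10	117068	0.27	186
rs9543325	13q22.1	T	C	1.66	true	0.44	256	0.85	5580	0.37	153016	0.46	370
rs4795218	HNF1B	G	A	0.53	true	0.20	256	0.06	82	0.21	2072	0.50	4
rs7190458	BCAR1	C	T	0.88	true	0.07	256	NA	NA	NA	NA	NA	NA
rs10094872	MYC	A	T	1.37	true	0.28	256	NA	NA	NA	NA	NA	NA
rs684559	CHI3L2	G	A	1.24	false	0.32	256	NA	NA	NA	NA	NA	NA
rs353630	CD44	G	A	0.95	false	0.29	256	NA	NA	NA	NA	NA	NA
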