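rsid	maf_controls	maf_cases	allelic_or	significant
rs11655237	0.13	0.14	1.06	false
rs2736098	0.25	0.22	0.79	false
rs351365	0.29	0.26	0.85	false
rs3790844	0.27	0.18	0.61	true
rs1486134	0.25	0.24	1.03	false
rs16986825	0.17	0.14	0.76	false
rs17688601	0.25	0.18	0.63	true
rs9581943	0.36	0.31	1.22	false
rs1561927	0.24	0.32	1.47	false
rs9854771	0.39	0.25	0.53	true
rs73328514	0.10	0.15	1.56	false
rs7310409	0.41	0.49	1.41	true
rs1517037	0.21	0.24	1.18	false
rs2853677	0.46	0.37	0.70	false
rs2941471	0.44	0.35	0.64	true
rs6971499	0.11	0.10	1.24	false
rs10991043	0.39	0.37	1.10	false
rs401681	0.45	0.54	1.53	true
rs13303010	0.22	0.37	1.88	true
rs9543325	0.44	0.56	1.66	true
rs4795218	0.20	0.11	0.53	true
rs7190458	0.07	0.08	0.88	false
rs10094872	0.28	0.34	1.37	false
rs684559	0.32	0.29	1.24	false
rs353630	0.29	0.30	0.95	false
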