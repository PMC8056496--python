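rsid	group	ancestry	maf	n
rs3790844	case	African	0.23	30
rs3790844	case	European	0.21	62
rs3790844	case	Asian	1.0	2
rs3790844	control	African	0.26	45
rs3790844	control	European	0.26	206
rs3790844	control	Asian	0.88	4
rs17688601	case	African	0.22	30
rs17688601	case	European	0.18	62
rs17688601	case	Asian	0.00	2
rs17688601	control	African	0.27	45
rs17688601	control	European	0.25	206
rs17688601	control	Asian	0.00	4
rs9854771	case	African	0.23	30
rs9854771	case	European	0.27	62
rs9854771	case	Asian	0.00	2
rs9854771	control	African	0.47	45
rs9854771	control	European	0.38	206
rs9854771	control	Asian	0.00	4
rs7310409	case	African	0.48	30
rs7310409	case	European	0.47	62
rs7310409	case	Asian	0.5	2
rs7310409	control	African	0.34	45
rs7310409	control	European	0.42	206
rs7310409	control	Asian	0.25	4
rs2941471	case	African	0.65	30
rs2941471	case	European	0.67	62
rs2941471	case	Asian	0.5	2
rs2941471	control	African	0.41	45
rs2941471	control	European	0.44	206
rs2941471	control	Asian	0.375	4
rs401681	case	African	0.42	30
rs401681	case	European	0.5	62
rs401681	case	Asian	0.5	2
rs401681	control	African	0.45	45
rs401681	control	European	0.45	206
rs401681	control	Asian	0.25	4
rs13303010	case	African	0.35	30
rs13303010	case	European	0.33	62
rs13303010	case	Asian	0.25	2
rs13303010	control	African	0.35	45
rs13303010	control	European	0.19	206
rs13303010	control	Asian	0.25	4
rs9543325	case	African	0.45	30
rs9543325	case	European	0.49	62
rs9543325	case	Asian	0.25	2
rs9543325	control	African	0.61	45
rs9543325	control	European	0.40	206
rs9543325	control	Asian	0.5	4
rs4795218	case	African	0.13	30
rs4795218	case	European	0.15	62
rs4795218	case	Asian	0.00	2
rs4795218	control	African	0.14	45
rs4795218	control	European	0.22	206
rs4795218	control	Asian	0.2	4
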