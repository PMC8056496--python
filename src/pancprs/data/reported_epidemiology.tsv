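variable	level	pct_cases	pct_controls
sex	male	41.0	43.0
sex	female	59.0	57.0
ethnicity	African	32.0	17.5
ethnicity	European	66.7	81.3
ethnicity	Asian	1.3	1.2
tobacco	yes	51.32	32.31
tobacco	no	48.68	67.69
alcohol	yes	31.58	32.31
alcohol	no	68.42	67.69
diabetes	yes	35.53	9.62
diabetes	no	64.47	90.38
pancreatitis	yes	10.53	0.77
pancreatitis	no	89.47	99.23
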