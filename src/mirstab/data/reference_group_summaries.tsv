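species	group	metric	n	mean	sd
human	S_n	amfe	132	44.1	14.1
human	S_c1	amfe	60	45.2	9.98
human	S_c2	amfe	66	44.6	7.06
human	S_c3	amfe	33	44.7	6.36
mouse	S_n	amfe	108	41.0	9.79
mouse	S_c1	amfe	63	45.1	7.83
mouse	S_c2	amfe	75	45.0	6.93
mouse	S_c3	amfe	39	43.8	5.89
chicken	S_n	amfe	21	42.2	14.7
chicken	S_c2	amfe	40	41.6	5.59
chicken	S_c3	amfe	19	42.3	5.05
human	S_n	bp_pct	132	68.66	7.83
human	S_c1	bp_pct	60	71.88	6.20
human	S_c2	bp_pct	66	72.94	5.64
human	S_c3	bp_pct	33	73.48	4.67
mouse	S_n	bp_pct	108	67.87	6.51
mouse	S_c1	bp_pct	63	72.53	5.85
mouse	S_c2	bp_pct	75	72.10	5.87
mouse	S_c3	bp_pct	39	73.37	5.13
chicken	S_n	bp_pct	21	68.24	7.37
chicken	S_c2	bp_pct	40	70.89	7.06
chicken	S_c3	bp_pct	19	73.08	5.14
human	S_n	au_pair_pct	132	42.73	16.12
human	S_c1	au_pair_pct	60	49.34	11.81
human	S_c2	au_pair_pct	66	48.67	8.17
human	S_c3	au_pair_pct	33	50.14	11.02
mouse	S_n	au_pair_pct	108	44.35	11.20
mouse	S_c1	au_pair_pct	63	48.20	11.47
mouse	S_c2	au_pair_pct	75	47.70	8.14
mouse	S_c3	au_pair_pct	39	50.85	10.93
chicken	S_n	au_pair_pct	21	37.13	17.43
chicken	S_c2	au_pair_pct	40	51.22	7.19
chicken	S_c3	au_pair_pct	19	53.80	7.56
human	S_n	AU_pct	132	47.11	13.18
human	S_c1	AU_pct	60	53.87	10.66
human	S_c2	AU_pct	66	51.62	7.15
human	S_c3	AU_pct	33	52.94	9.67
mouse	S_n	AU_pct	108	49.30	9.65
mouse	S_c1	AU_pct	63	53.07	9.42
mouse	S_c2	AU_pct	75	50.57	6.77
mouse	S_c3	AU_pct	39	53.05	9.15
chicken	S_n	AU_pct	21	44.17	14.75
chicken	S_c2	AU_pct	40	55.11	4.99
chicken	S_c3	AU_pct	19	57.18	5.72
human	S_n	A_pct	132	22.10	7.89
human	S_c1	A_pct	60	23.78	6.36
human	S_c2	A_pct	66	23.41	4.74
human	S_c3	A_pct	33	22.96	6.05
mouse	S_n	A_pct	108	22.40	6.16
mouse	S_c1	A_pct	63	23.29	5.42
mouse	S_c2	A_pct	75	22.90	4.57
mouse	S_c3	A_pct	39	22.89	5.90
chicken	S_n	A_pct	21	19.47	8.79
chicken	S_c2	A_pct	40	24.60	4.14
chicken	S_c3	A_pct	19	24.45	5.26
human	S_n	U_pct	132	25.01	6.96
human	S_c1	U_pct	60	30.09	6.42
human	S_c2	U_pct	66	28.21	4.42
human	S_c3	U_pct	33	29.98	6.16
mouse	S_n	U_pct	108	26.90	5.97
mouse	S_c1	U_pct	63	29.78	6.11
mouse	S_c2	U_pct	75	27.67	4.40
mouse	S_c3	U_pct	39	30.16	5.51
chicken	S_n	U_pct	21	24.69	8.01
chicken	S_c2	U_pct	40	30.52	3.97
chicken	S_c3	U_pct	19	32.74	3.26
human	S_n	G_pct	132	27.49	7.90
human	S_c1	G_pct	60	24.45	5.53
human	S_c2	G_pct	66	25.71	3.49
human	S_c3	G_pct	33	26.06	5.15
mouse	S_n	G_pct	108	27.28	5.57
mouse	S_c1	G_pct	63	25.30	5.28
mouse	S_c2	G_pct	75	26.28	3.72
mouse	S_c3	G_pct	39	26.06	5.06
chicken	S_n	G_pct	21	29.35	6.00
chicken	S_c2	G_pct	40	24.80	3.53
chicken	S_c3	G_pct	19	23.94	4.49
human	S_n	C_pct	132	25.40	7.24
human	S_c1	C_pct	60	21.68	5.84
human	S_c2	C_pct	66	22.67	5.11
human	S_c3	C_pct	33	20.99	5.92
mouse	S_n	C_pct	108	23.42	5.74
mouse	S_c1	C_pct	63	21.62	5.16
mouse	S_c2	C_pct	75	23.15	5.02
mouse	S_c3	C_pct	39	20.90	5.53
chicken	S_n	C_pct	21	26.48	9.74
chicken	S_c2	C_pct	40	20.08	3.24
chicken	S_c3	C_pct	19	18.87	3.33
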