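patient_id	sex	age	tnm	n_missense	n_indel	n_neoantigen
NAG1606003	M	71	T4bN2M1	190	11	323
NAG1606008	M	80	T4bN2M0	158	35	208
NAG1606009	M	62	T4bN1M0	109	7	133
NAG1606010	M	68	T2N0M0	182	20	134
NAG1606011	F	45	T4aN3bM0	1336	59	2121
S0616092301	F	54	T4bN1M0	9	5	4
S0616092302	F	58	T4aN1M0	145	31	242
S0616092903	M	61	T2N1M0	115	8	190
S0616092904	M	76	T4bN3aM0	217	12	297
S0616093001	M	67	T4aN1M	233	24	223
S0616101201	M	65	T4aN0M0	102	17	134
S0616101301	M	38	T4bN2M0	77	9	37
S0616101302	M	73	T4bN1M0	124	17	351
S0616101901	F	52	T4aN2M0	63	12	83
S0616102501	F	57	T2N2M0	128	16	220
S0616102502	M	66	T1aN1M0	177	9	666
S0616102601	F	62	T4bN2M0	78	9	70
S0616102602	M	49	T4bN2M0	150	14	206
S0616102801	F	50	T4bNM0	1672	104	4896
S0616110101	M	64	T4bN3aM0	331	43	313
S0616110401	F	41	T4bN3aM0	89	9	57
S0616110801	F	51	T4Bn3aM0	17	14	32
S0616110901	F	50	T2N3aM0	153	6	198
S0616111101	M	59	T1aN1M0	215	8	334
S0616111501	M	62	T4bN1M0	127	7	186
S0616111801	F	60	T4bN3aM0	70	9	85
S0616112401	M	58	T2N3bM0	131	7	211
S0616112901	M	54	T4bN1M0	78	22	122
S0616121301	M	42	T4bN3aM0	125	9	127
S0617010301	M	64	T2N2M0	258	16	116
S0617020601	M	60	T2N1M0	308	39	306
S0617020701	M	63	T4bN2M1	427	50	327
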