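category	mirna_id	rel_pct_myotubes	sig_diff	rel_cell_count	sig_count
inhibited	hsa-mir-100	56.13	***	97.25	*
inhibited	hsa-mir-106a/hsa-mir-17	69.91	***	93.99	***
inhibited	hsa-mir-1227	7.12	***	91.11	*
inhibited	hsa-mir-1233	11.88	***	73.07	***
inhibited	hsa-mir-125b	21.37	***	80.27	***
inhibited	hsa-mir-1267	2.37	***	75.12	***
inhibited	hsa-mir-130b*	27.31	***	86.11	***
inhibited	hsa-mir-138-1*	57.01	***	80.1	***
inhibited	hsa-mir-145	23.75	***	83.88	***
inhibited	hsa-mir-1538	19	***	85.59	***
inhibited	hsa-mir-18b*	15.44	***	75.64	***
inhibited	hsa-mir-223	30.88	***	92.11	ns
inhibited	hsa-mir-296-5p	23.75	***	93.31	**
inhibited	hsa-mir-326	14.25	***	94.34	***
inhibited	hsa-mir-331-3p	4.75	***	90.22	***
inhibited	hsa-mir-339-5p	66.39	***	92.79	**
inhibited	hsa-mir-365	7.13	***	77.53	***
inhibited	hsa-mir-429	54.63	***	85.25	***
inhibited	hsa-mir-454	33.25	***	87.31	ns
inhibited	hsa-mir-455-3p	42.76	***	96.4	ns
inhibited	hsa-mir-484	4.83	***	78.73	ns
inhibited	hsa-mir-485-3p	4.75	***	71.49	***
inhibited	hsa-mir-501-3p	69.25	***	91.25	***
inhibited	hsa-mir-512-5p	21.37	***	72.89	***
inhibited	hsa-mir-532-3p	9.5	***	85.93	***
inhibited	hsa-mir-541	69.87	***	97.77	ns
inhibited	hsa-mir-600	35.63	***	93.48	ns
inhibited	hsa-mir-625*	28.5	***	72.89	***
inhibited	hsa-mir-636	2.37	***	81.98	***
inhibited	hsa-mir-663	21.38	***	84.73	***
inhibited	hsa-mir-664	7.13	***	82.85	***
inhibited	hsa-mir-766	45.13	***	73.24	***
inhibited	hsa-mir-770-5p	19	***	75.47	***
inhibited	hsa-mir-93*	9.5	***	92.1	ns
inhibited_low_count	hsa-let-7b*	4.75	***	28.64	***
inhibited_low_count	hsa-mir-1224-3p	2.38	***	51.46	***
inhibited_low_count	hsa-mir-1228	2.38	**	9.43	***
inhibited_low_count	hsa-mir-1249	1.66	***	53.17	***
inhibited_low_count	hsa-mir-125a-5p	19	***	69.8	***
inhibited_low_count	hsa-mir-1260	7.12	***	61.75	***
inhibited_low_count	hsa-mir-1280	11.88	***	68.95	***
inhibited_low_count	hsa-mir-129-3p	9.5	***	65.64	ns
inhibited_low_count	hsa-mir-1296	9.5	***	36.36	***
inhibited_low_count	hsa-mir-133a/hsa-mir-133b	42.75	*	0.85	***
inhibited_low_count	hsa-mir-150	4.75	***	60.37	***
inhibited_low_count	hsa-mir-197	4.75	***	27.79	***
inhibited_low_count	hsa-mir-204	2.85	***	27.44	***
inhibited_low_count	hsa-mir-328	0.1	**	30.87	***
inhibited_low_count	hsa-mir-342-3p	33.25	***	58.83	***
inhibited_low_count	hsa-mir-346	7.13	***	69.13	***
inhibited_low_count	hsa-mir-361-3p	4.51	***	9.6	***
inhibited_low_count	hsa-mir-483-3p	3.56	***	68.61	***
inhibited_low_count	hsa-mir-486-5p	2.85	***	34.48	***
inhibited_low_count	hsa-mir-574-3p	2.61	***	43.22	***
inhibited_low_count	hsa-mir-629*	16.62	***	67.23	***
inhibited_low_count	hsa-mir-885-5p	4.75	***	43.73	***
inhibited_high_count	hsa-mir-193b	38.04	***	102.74	*
inhibited_high_count	hsa-mir-369-3p	61.75	***	103.6	*
inhibited_high_count	hsa-mir-381	61.75	***	105.31	*
inhibited_high_count	hsa-mir-886-5p	38.04	***	112.86	***
inhibited_high_count	hsa-mir-940	21.37	***	112.35	***
enhanced	hsa-mir-98	104.51	*	87.82	***
high_count	hsa-mir-631	92.63	**	103.43	***
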