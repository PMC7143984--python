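split	id	set
1	1	training
1	4	training
1	6	training
1	7	training
1	8	training
1	9	training
1	12	training
1	13	training
1	14	training
1	15	training
1	16	training
1	17	training
1	18	training
1	19	training
1	20	training
1	21	training
1	23	training
1	25	training
1	27	training
1	29	training
1	30	training
1	31	training
1	33	training
1	34	training
1	36	training
1	37	training
1	38	training
1	40	training
1	41	training
1	42	training
1	45	training
1	46	training
1	48	training
1	51	training
1	52	training
1	54	training
1	55	training
1	56	training
1	57	training
1	59	training
1	60	training
1	61	training
1	63	training
1	64	training
1	65	training
1	67	training
1	69	training
1	70	training
1	73	training
1	74	training
1	75	training
1	77	training
1	90	training
1	94	training
1	98	training
1	99	training
1	109	training
1	112	training
1	116	training
1	117	training
1	118	training
1	120	training
1	121	training
1	122	training
1	123	training
1	124	training
1	126	training
1	130	training
1	136	training
1	2	validation
1	3	validation
1	5	validation
1	10	validation
1	11	validation
1	22	validation
1	26	validation
1	32	validation
1	35	validation
1	39	validation
1	43	validation
1	47	validation
1	68	validation
1	71	validation
1	92	validation
1	103	validation
1	125	validation
1	143	validation
2	1	training
2	6	training
2	7	training
2	8	training
2	9	training
2	12	training
2	13	training
2	14	training
2	15	training
2	16	training
2	18	training
2	19	training
2	23	training
2	25	training
2	27	training
2	31	training
2	33	training
2	34	training
2	36	training
2	40	training
2	41	training
2	42	training
2	45	training
2	46	training
2	48	training
2	51	training
2	54	training
2	55	training
2	56	training
2	57	training
2	59	training
2	61	training
2	63	training
2	65	training
2	67	training
2	69	training
2	73	training
2	74	training
2	75	training
2	77	training
2	98	training
2	109	training
2	112	training
2	116	training
2	117	training
2	121	training
2	123	training
2	124	training
2	130	training
2	136	training
2	5	training
2	10	training
2	11	training
2	22	training
2	26	training
2	32	training
2	39	training
2	43	training
2	47	training
2	68	training
2	71	training
2	92	training
2	103	training
2	125	training
2	143	training
2	4	validation
2	17	validation
2	20	validation
2	21	validation
2	29	validation
2	30	validation
2	37	validation
2	38	validation
2	52	validation
2	60	validation
2	64	validation
2	70	validation
2	90	validation
2	94	validation
2	99	validation
2	118	validation
2	120	validation
2	122	validation
2	126	validation
2	2	validation
2	3	validation
2	35	validation
3	1	training
3	4	training
3	6	training
3	7	training
3	8	training
3	9	training
3	12	training
3	13	training
3	14	training
3	15	training
3	16	training
3	17	training
3	18	training
3	19	training
3	21	training
3	23	training
3	25	training
3	27	training
3	29	training
3	31	training
3	36	training
3	37	training
3	38	training
3	40	training
3	41	training
3	42	training
3	45	training
3	48	training
3	51	training
3	54	training
3	56	training
3	57	training
3	59	training
3	60	training
3	64	training
3	65	training
3	69	training
3	70	training
3	73	training
3	74	training
3	75	training
3	77	training
3	94	training
3	98	training
3	99	training
3	109	training
3	116	training
3	118	training
3	121	training
3	124	training
3	130	training
3	136	training
3	2	training
3	5	training
3	10	training
3	11	training
3	26	training
3	32	training
3	35	training
3	39	training
3	43	training
3	47	training
3	68	training
3	71	training
3	125	training
3	143	training
3	20	validation
3	30	validation
3	33	validation
3	34	validation
3	46	validation
3	52	validation
3	55	validation
3	61	validation
3	63	validation
3	67	validation
3	90	validation
3	112	validation
3	117	validation
3	120	validation
3	122	validation
3	123	validation
3	126	validation
3	3	validation
3	22	validation
3	92	validation
3	103	validation
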