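id	age	histology	site	snv	indels	dn_ds	ts_tv	pct_scna	clonality
OS-046	10	Mixed	Femur	91	24	2.8	1.76	67.45	3
OS-059	13	Osteoblastic	Fibula	50	29	1.18	1.38	67.1	4
OS-061	12	Chondroblastic	Femur	106	36	1.8	1.65	67.5	7
OS-063	17	Teleangiectatic	Humerus	127	48	1.13	1.75	64.3	6
OS-065	15	Osteoblastic	Tibia	78	34	1.75	1.43	44.2	3
OS-079	45	Osteoblastic	Femur	48	20	2.35	1.17	56.2	2
OS-224	11	Osteoblastic	Tibia	310	397	1.62	1.64	57.1	14
OS-225	14	Osteoblastic	Tibia	38	25	1	1.53	50.8	2
OS-226	11	Osteoblastic	Tibia	52	36	1.77	1.36	57.8	6
OS-227	19	Osteoblastic	Femur	29	32	3	1.41	0.2	3
OS-228	13	Chondroblastic	Femur	48	24	2	1.28	59.3	4
OS-230	18	Chondroblastic	Tibia	192	185	1.5	1.23	62.5	11
OS-231	13	Chondroblastic	Tibia	195	246	1.39	1.18	81.8	8
OS-232	21	Extraosseous	Femur	606	529	2.59	1.18	61.1	16
OS-234	17	Osteoblastic	Humerus	46	20	3.8	1.29	60.5	4
OS-235	14	Osteoblastic	Tibia	52	23	1.7	0.79	76.2	5
OS-236	19	Chondroblastic	Femur	46	37	2.6	1.29	59.4	5
OS-237	14	Chondroblastic	Femur	29	28	1.33	1.89	44.9	5
OS-238	17	Osteoblastic	Tibia	63	33	2	2.49	38.3	6
OS-240	15	Osteoblastic	Femur	32	19	3.75	1.66	15.6	6
OS-241	5	Osteoblastic	Fibula	7	19		0.4		2
OS-242	14	Osteoblastic	Tibia	35	17	7.33	0.94	26.4	4
OS-250	14	Osteoblastic	Femur	70	35	1.25	0.79	20.5	4
OS-251	9	Osteoblastic	Femur	106	38	1.64	0.89	0.2	9
OS-252	16	Chondroblastic	Femur	253	33	0.82	2.37	34.7	4
OS-253	6	Chondroblastic	Tibia	71	47	3.33	0.82	56.7	3
OS-253M	6	Chondroblastic	Lung	167	56	2.15	0.77	70.1	12
OS-254	27	Mixed	Fibula	33	20	1.25	2.14	30.1	1
OS-255	12	Chondroblastic	Tibia	3153	459	2.56	2.01	33.9	7
OS-256	17	Osteoblastic	Tibia	50	44	2	1.78	55.6	4
OS-257	12	Mixed	Tibia	1993	345	1.35	1.92	17.6	4
OS-258	20	Unknown	Humerus	104	29	2.22	1.66	29.4	7
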