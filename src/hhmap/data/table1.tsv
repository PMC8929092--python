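family	total_affected	genotyped_affected	total_unaffected	genotyped_unaffected
3	6	5	84	29
4	5	5	37	23
5	8	5	79	22
9	9	8	64	22
12	3	3	19	3
21	5	5	53	19
26	6	3	43	13
44	3	3	14	9
45	6	4	36	15
58	3	2	27	14
61	7	6	40	17
81	3	3	23	8
2360	16	11	136	26
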