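family	rchh_region	chr	start	end	ref	alt	function	gene	affected	unaffected
61	chr6:42767957-43333769	6	43181034	43181034	T	G	splicing region on exon 27	CUL9	3 out of 3	1 out of 1
61	chr6:42767957-43333769	6	43106964	43106964	A	C	non-synonymous variant on exon 9	PTK7	3 out of 3	0 out of 1
61	chr6:42767957-43333769	6	43223539	43223539	A	C	non-synonymous variant on exon 9	TTBK1	3 out of 3	0 out of 1
61	chr6:42767957-43333769	6	42976917	42976917	A	C	non-synonymous variant on exon 9	PPP2R5D	3 out of 3	0 out of 1
61	chr20:48202462-49044808	20	49366933	49366933	G	C	non-synonymous variant on exon 3	PARD6B	3 out of 3	0 out of 1
61	chr20:49044993-50323395	20	50245517	50245517	A	C	splicing region on exon 16	ATP9A	3 out of 3	1 out of 1
61	chr12:122479650-122743242	12	123943942	123943942	A	C	intronic variant	SNRNP35	3 out of 3	0 out of 1
61	chr2:221458760-223560597	2	223554057	223554057	T	G	non-synonymous variant on exon 3	MOGAT1	3 out of 3	1 out of 1
2360	chr6:26287459-32628250	6	29856257	29856257	G	C	non-coding RNA	HLA-H	6 out of 10	NA
2360	chr6:26287459-32628250	6	29856261	29856261	G	A	non-coding RNA	HLA-H	6 out of 10	NA
2360	chr6:26287459-32628250	6	29856263	29856263	G	A	non-coding RNA	HLA-H	6 out of 10	NA
2360	chr13:108090996-108968251	13	108519067	108519070	CTCT	-	5′UTR	FAM155A (NLF-1)	9 out of 10	NA
2360	chr13:108090996-108968251	13	109859349	109859354	TGTGTT	-	3′UTR	MYO16	7 out of 10	NA
4	chr21:42351204-42525479	21	43557751	43557832			deletion on slicing site	UMODL1	3 out of 4	NA
5	chr13:109945232-110218960	13	11364877	11364877	-	GGG	insertion in the upstream site	ING1	3 out of 5	NA
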