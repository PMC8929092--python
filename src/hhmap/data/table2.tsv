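family	patient_share	control_share	chr	bp_range	snp_range	neg_log10_p
2360	6 out of 11	7 out of 26	1	20024018-20110347	rs12405947-rs10492999	1.20
2360	8 out of 11	11 out of 26	3	127665610-128219449	rs1687462-rs9826526	1.23
2360	5 out of 11	5 out of 26	6	26287459-32628250	rs4458680-rs11757159	1.25
2360	7 out of 11	9 out of 26	11	16548170-17019030	rs4593976-rs7942085	1.20
2360	11 out of 11	19 out of 26	13	106416156-106713791	rs9555302-rs1819243	1.30
2360	11 out of 11	18 out of 26	13	106716741-106978764	rs3949948-rs16970623	1.47
2360	11 out of 11	19 out of 26	13	106979630-106979630	rs1830754-rs1830754	1.30
2360	11 out of 11	18 out of 26	13	106979661-108046934	rs2076766-rs7992149	1.47
2360	11 out of 11	19 out of 26	13	108048315-108048315	rs9583266-rs9583266	1.30
2360	11 out of 11	18 out of 26	13	108050353-108090301	rs12586075-rs16972849	1.47
2360	11 out of 11	17 out of 26	13	108090996-108968251	rs16972855-rs9521415	1.63
2360	7 out of 11	9 out of 26	22	43217334-43366873	rs133807-rs138628	1.20
61	5 out of 6	7 out of 17	2	221458760-223560597	rs634813-rs1440063	1.22
61	6 out of 6	10 out of 17	4	181036139-181598064	rs7655585-rs2727426	1.23
61	6 out of 6	10 out of 17	5	31060610-31060610	rs1392428-rs1392428	1.23
61	5 out of 6	7 out of 17	6	42767957-43333769	rs394754-rs7752120	1.22
61	5 out of 6	7 out of 17	6	45282619-46437363	rs7762957-rs1372567	1.22
61	4 out of 6	4 out of 17	6	62416537-67861137	rs213824-rs9294736	1.38
61	4 out of 6	4 out of 17	6	100591693-100883678	rs9399393-rs2658132	1.38
61	5 out of 6	7 out of 17	7	8552281-8768564	rs1859275-rs10268580	1.22
61	6 out of 6	9 out of 17	9	8991207-8991239	rs10511519-rs10816028	1.41
61	6 out of 6	8 out of 17	9	8991538-8994896	rs10511520-rs10816029	1.61
61	6 out of 6	9 out of 17	9	9000336-9395003	rs7025315-rs10759064	1.41
61	6 out of 6	10 out of 17	9	9395316-11328859	rs1475680-rs17788370	1.23
61	6 out of 6	10 out of 17	9	12662320-13015284	rs1408801-rs10514822	1.23
61	5 out of 6	7 out of 17	9	115676064-115712622	rs6478042-rs7034929	1.22
61	6 out of 6	10 out of 17	9	134997809-134997809	rs626713-rs626713	1.23
61	6 out of 6	10 out of 17	12	122479650-122743242	rs1706477-rs7137946	1.23
61	6 out of 6	10 out of 17	12	127998742-128288581	rs11060036-rs10847807	1.23
61	5 out of 6	7 out of 17	16	84533519-84542101	rs305059-rs908988	1.22
61	5 out of 6	6 out of 17	20	48202462-49044808	rs6020298-rs6122991	1.43
61	5 out of 6	7 out of 17	20	49044993-50323395	rs11904901-rs6068117	1.22
61	5 out of 6	6 out of 17	20	50326580-50563902	rs6021835-rs2024650	1.43
45	4 out of 4	7 out of 15	1	22014570-23032859	rs2010397-rs4654821	1.22
45	3 out of 4	4 out of 15	7	54280160-56646646	rs13438238-rs2634081	1.21
45	4 out of 4	7 out of 15	13	72551882-73411123	rs4883922-rs728926	1.22
45	4 out of 4	6 out of 15	13	73411181-75116077	rs17288193-rs1006412	1.40
44	3 out of 3	3 out of 9	1	2289487-2455004	rs7545940-rs9803764	1.24
44	3 out of 3	3 out of 9	1	156653770-160351933	rs2188102-rs1415259	1.24
44	3 out of 3	3 out of 9	2	138041133-138458405	rs7563139-rs10199542	1.24
44	3 out of 3	3 out of 9	4	96765575-103179634	rs11941922-rs2129294	1.24
44	3 out of 3	3 out of 9	5	73747-556484	rs7709758-rs6420045	1.24
44	3 out of 3	3 out of 9	5	150483977-150816773	rs2303027-rs17802828	1.24
44	3 out of 3	3 out of 9	5	154874578-156864954	rs1295243-rs2277027	1.24
44	3 out of 3	3 out of 9	7	142903019-142909027	rs6963381-rs1880560	1.24
44	3 out of 3	3 out of 9	8	602758-3038563	rs9314595-rs13261550	1.24
44	3 out of 3	3 out of 9	16	10909415-11580966	rs2229321-rs8050461	1.24
26	3 out of 3	3 out of 13	1	171619320-173691804	rs6701066-rs860905	1.65
26	3 out of 3	4 out of 13	1	173695580-174106457	rs1016815-rs10798418	1.40
26	3 out of 3	4 out of 13	14	80069595-82872217	rs1543918-rs17625929	1.40
21	5 out of 5	10 out of 19	1	14226898-14226898	rs4579751-rs4579751	1.27
21	5 out of 5	10 out of 19	5	73478194-73598034	rs2120729-rs1460812	1.27
9	4 out of 8	4 out of 22	11	45356859-51450167	rs717653-rs12291581	1.31
9	4 out of 8	4 out of 22	12	44020977-44336606	rs10785572-rs878111	1.31
9	7 out of 8	10 out of 22	21	27810551-29354016	rs2830992-rs1064019	1.48
5	3 out of 5	4 out of 22	5	58726008-59841224	rs525099-rs40512	1.41
5	4 out of 5	8 out of 22	9	85066453-85227053	rs10867967-rs871790	1.21
5	4 out of 5	7 out of 22	9	85228118-85448505	rs3860918-rs1052690	1.39
5	5 out of 5	12 out of 22	13	109106993-109251608	rs9515092-rs7986346	1.22
5	5 out of 5	11 out of 22	13	109253434-109607383	rs11069806-rs9521623	1.36
5	4 out of 5	8 out of 22	13	109945232-110218960	rs9555712-rs12865465	1.21
4	5 out of 5	12 out of 23	1	237070145-237394008	rs869035-rs1980004	1.30
4	5 out of 5	11 out of 23	1	237395275-238575190	rs11808376-rs10495466	1.43
4	5 out of 5	12 out of 23	1	238576784-238576784	rs7552602-rs7552602	1.30
4	5 out of 5	11 out of 23	1	238579605-238713399	rs12137050-rs9662136	1.43
4	5 out of 5	11 out of 23	7	142336895-143056687	rs4236481-rs12540188	1.43
4	5 out of 5	12 out of 23	7	143059971-143855577	rs4640977-rs2057868	1.30
4	5 out of 5	11 out of 23	7	143858588-144083589	rs17169930-rs7793227	1.43
4	5 out of 5	12 out of 23	7	144088382-145211344	rs6954142-rs4601231	1.30
4	5 out of 5	12 out of 23	8	126600646-126663920	rs4006563-rs7016867	1.30
4	5 out of 5	12 out of 23	8	126672376-128144872	rs4870946-rs1456314	1.30
4	5 out of 5	12 out of 23	13	109370211-109416832	rs7323507-rs7984646	1.30
4	5 out of 5	11 out of 23	13	109419064-109607383	rs9583447-rs9521623	1.43
4	5 out of 5	11 out of 23	14	92683815-94120061	rs12589195-rs12880862	1.43
4	5 out of 5	12 out of 23	14	94122073-94216494	rs2069956-rs7148204	1.30
4	5 out of 5	12 out of 23	17	67527147-67755206	rs9914764-rs12939271	1.30
4	5 out of 5	12 out of 23	21	42351204-42525479	rs17114247-rs881395	1.30
4	5 out of 5	11 out of 23	21	42525851-42616108	rs915846-rs691567	1.43
4	5 out of 5	12 out of 23	22	24549605-24559502	rs4820658-rs4822661	1.30
4	5 out of 5	12 out of 23	22	24561312-24579927	rs17704912-rs2748234	1.30
3	3 out of 5	6 out of 29	1	171432870-171774723	rs1234313-rs1461019	1.30
3	1 out of 5	1 out of 29	2	90959860-91680834	rs10201040-rs4373803	1.23
3	5 out of 5	14 out of 29	3	71749225-72031216	rs864380-rs9861583	1.38
3	5 out of 5	15 out of 29	3	72031489-72458673	rs1995453-rs4303823	1.27
3	5 out of 5	14 out of 29	3	72459498-74148704	rs6790069-rs1405396	1.38
3	5 out of 5	14 out of 29	3	74710393-74710393	rs13073838-rs13073838	1.38
3	4 out of 5	10 out of 29	3	75820822-76074141	rs536575-rs4095546	1.27
3	1 out of 5	1 out of 29	5	69782071-69967168	rs169717-rs3871460	1.23
3	4 out of 5	10 out of 29	6	52061483-52205031	rs6906409-rs6913472	1.27
3	4 out of 5	9 out of 29	6	52205660-52213626	rs9395771-rs9382084	1.42
3	5 out of 5	10 out of 29	7	4275511-4316475	rs10272180-rs2107834	1.96
3	5 out of 5	11 out of 29	7	4318943-4930528	rs2097884-rs2089967	1.79
3	5 out of 5	12 out of 29	7	4930906-4930906	rs6947947-rs6947947	1.64
3	5 out of 5	11 out of 29	7	4934189-5342068	rs13224720-rs10234709	1.79
3	5 out of 5	12 out of 29	7	5344404-5549582	rs13238999-rs2098225	1.64
3	5 out of 5	13 out of 29	7	5551125-6459404	rs1725213-rs7810553	1.50
3	5 out of 5	14 out of 29	7	6461542-7642706	rs7792987-rs10280185	1.38
3	5 out of 5	15 out of 29	7	7767212-7831276	rs17137412-rs12702661	1.27
3	5 out of 5	15 out of 29	7	150524562-150524562	rs310586-rs310586	1.27
3	5 out of 5	14 out of 29	7	150526978-150611097	rs7458773-rs6953552	1.38
3	5 out of 5	15 out of 29	7	150613053-150619105	rs7797007-rs219245	1.27
3	1 out of 5	1 out of 29	9	40059290-44362584	rs375972-rs4929023	1.23
3	1 out of 5	1 out of 29	9	44670536-46992793	rs12006135-rs7049015	1.23
3	1 out of 5	1 out of 29	9	65231255-65635106	rs28533023-rs1480368	1.23
3	1 out of 5	1 out of 29	13	111553045-114123122	rs12017986-rs12874290	1.23
3	1 out of 5	1 out of 29	20	28039018-28259678	rs7267880-rs6567465	1.23
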