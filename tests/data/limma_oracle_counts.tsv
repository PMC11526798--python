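	s00	s01	s02	s03	s04	s05	s06	s07	s08	s09	s10	s11	s12	s13	s14	s15	s16	s17	s18	s19
g000	504	429	716	460	162	205	245	170	331	352	507	384	271	323	413	262	731	989	954	806
g001	16	33	4	18	8	10	20	34	6	24	47	7	80	36	8	10	60	88	32	67
g002	36	27	28	38	16	22	24	20	23	27	18	23	98	90	87	111	42	18	18	35
g003	971	1096	1141	795	1720	1474	1874	1576	517	367	503	660	1091	1208	1076	1108	1959	1837	1754	1520
g004	4816	3754	5308	5256	1974	627	706	1657	3135	1348	4351	1451	5344	5279	10559	3989	8556	14729	12726	83680
g005	17	12	17	12	22	22	12	8	7	9	9	16	4	4	4	4	8	14	15	19
g006	3	7	5	7	1	1	0	1	8	5	6	4	6	10	8	5	3	2	9	1
g007	12	16	5	14	189	161	144	171	0	1	3	1	9	15	8	14	17	10	11	12
g008	64	46	36	56	94	141	59	66	8	13	11	9	17	57	33	40	4	0	9	12
g009	9	10	10	22	10	10	11	12	22	11	23	9	17	18	11	13	11	5	22	14
g010	200	264	236	111	335	381	257	294	240	291	174	343	307	414	263	419	252	171	89	272
g011	392	233	199	262	41	41	57	44	51	71	91	133	396	173	531	328	71	77	58	78
g012	14	2	3	12	6	3	4	2	11	3	2	9	3	7	6	7	31	28	21	26
g013	189	206	242	210	384	358	349	317	109	140	108	136	240	246	270	208	15	11	13	5
g014	3	7	1	4	5	3	0	0	5	1	3	5	0	0	1	0	1	4	1	2
g015	84	130	76	93	138	75	48	119	348	217	349	275	141	106	170	148	670	774	676	572
g016	1827	2264	1233	1606	13373	9356	7093	34674	614	682	684	214	1406	5728	3409	1248	1484	987	2104	3838
g017	1399	734	1083	1514	1143	1127	1206	1504	477	883	333	634	2009	1845	1609	3031	2345	1946	2784	1987
g018	276	221	180	273	61	45	53	39	703	600	449	837	102	137	133	69	695	699	965	814
g019	41	35	36	51	57	42	50	52	45	32	26	27	347	290	349	298	83	99	85	117
g020	10	16	19	36	14	8	20	3	8	9	5	18	21	15	24	19	14	10	19	30
g021	95	86	96	68	89	92	106	65	91	86	78	69	69	90	70	83	83	104	72	75
g022	39	11	19	8	26	27	33	20	23	41	38	21	110	7	36	36	17	32	12	31
g023	1635	1947	2005	1464	1806	1443	1643	1638	1829	1530	1596	1742	1680	1665	1368	1459	1883	1570	1359	1670
g024	13	25	23	17	18	14	10	17	23	19	10	21	14	13	11	11	18	18	11	23
g025	18	50	20	20	33	13	34	16	16	26	10	18	10	29	42	22	27	19	41	28
g026	1234	1006	988	1012	1775	1554	760	1011	1585	766	938	911	891	1617	1116	1077	1078	859	1030	1365
g027	24	25	29	37	27	28	19	24	31	47	22	25	19	23	31	18	36	27	21	25
g028	21	25	20	23	25	38	21	15	24	22	24	12	36	19	35	37	30	38	14	26
g029	8	5	7	7	10	8	7	8	3	6	10	9	3	11	3	9	5	2	9	5
g030	139	225	106	29	38	197	45	14	44	91	117	115	84	157	129	127	55	111	134	18
g031	21	23	20	20	20	24	20	20	25	10	37	19	15	20	23	24	37	31	15	20
g032	1617	3223	592	2204	1418	2088	1004	1556	1005	2485	2674	2337	1327	3540	3098	1611	1856	2096	2229	2932
g033	13	14	59	56	23	27	27	52	14	15	23	15	17	83	6	30	37	10	34	16
g034	1240	529	863	1026	1153	596	988	330	496	646	1827	969	847	779	798	477	591	1001	723	888
g035	275	24	273	28	125	41	326	140	214	128	40	69	101	177	59	268	105	43	112	44
g036	86	115	89	128	97	88	87	78	152	100	157	97	71	92	105	165	81	88	101	74
g037	1185	1756	3182	5044	3645	5474	1600	954	4088	2675	7374	3434	4164	5943	6069	6786	3236	1015	885	1146
g038	1522	2594	1847	1796	2504	2337	2266	1973	1989	2433	1865	1923	2080	2097	2175	2025	2534	2085	2269	1838
g039	11	7	8	9	9	7	7	4	4	4	4	5	6	11	7	6	5	13	2	8
g040	12	20	18	53	23	6	20	32	12	17	12	38	25	24	36	17	39	27	16	41
g041	37	11	9	17	8	14	16	22	30	24	17	16	12	9	19	9	26	10	7	26
g042	1733	2213	3486	2328	1802	1139	2068	2536	1724	1276	1618	2112	1961	1616	2432	3522	2641	1456	1987	1882
g043	191	159	228	152	162	203	90	260	267	356	193	182	189	213	208	134	138	209	278	129
g044	52	15	17	46	27	16	17	23	25	79	42	80	61	24	63	57	77	36	45	39
g045	1311	1169	1786	1404	1626	1022	1229	1088	1119	1159	1276	1297	1094	1281	1227	1241	1510	1239	1717	1491
g046	41	6	80	63	44	26	10	27	49	9	24	26	52	32	44	45	58	72	49	16
g047	459	497	446	461	552	320	345	389	495	411	442	530	395	425	527	445	473	378	472	382
g048	17	15	17	16	23	25	13	19	20	13	24	23	31	23	18	19	17	12	28	16
g049	1	2	9	3	7	3	2	3	2	2	3	7	10	3	3	11	5	4	7	4
g050	274	465	307	595	517	557	574	584	607	376	525	585	291	600	482	470	439	619	763	383
g051	16	43	15	48	12	22	57	19	58	8	58	30	7	44	37	41	64	13	71	23
g052	65	49	29	43	22	44	22	32	52	44	42	39	47	45	16	46	51	34	39	45
g053	29	34	24	21	23	34	29	25	23	22	20	31	26	29	23	21	32	28	20	29
g054	27	49	37	16	10	4	11	16	19	41	24	13	24	23	28	22	24	28	30	19
g055	167	191	185	291	153	263	372	150	165	271	294	313	200	153	149	190	148	344	59	165
g056	52	42	35	35	39	33	26	46	40	30	48	30	43	38	45	41	39	52	27	50
g057	76	46	35	128	75	87	69	33	48	74	90	46	56	76	113	68	43	65	57	97
g058	6	29	26	17	16	8	15	14	7	12	12	28	12	6	13	10	13	12	7	15
g059	41	230	272	223	98	108	163	221	141	79	52	128	199	100	36	24	82	16	279	49
g060	250	323	273	186	203	185	215	237	172	147	277	203	187	220	205	254	475	234	313	189
g061	61	80	33	108	60	64	92	123	39	86	81	60	65	104	93	46	62	48	45	56
g062	59	31	72	35	77	75	49	55	44	115	71	43	76	70	42	103	41	65	60	109
g063	3170	2704	2885	3171	2321	3550	2108	3679	2985	1695	2890	2059	2451	2030	2580	2743	3313	2022	1883	3016
g064	5	2	3	8	10	5	3	6	4	8	13	8	8	8	8	10	5	5	6	7
g065	34	39	48	64	19	26	42	31	36	58	48	43	25	53	26	48	24	24	19	55
g066	156	192	203	121	256	147	132	104	141	154	151	118	99	136	182	104	199	170	147	106
g067	229	129	467	203	159	348	360	335	307	196	280	293	291	341	323	144	136	315	200	217
g068	13	5	1	2	4	8	5	10	10	3	6	4	1	2	6	8	8	3	6	1
g069	32	16	50	29	28	27	30	11	31	22	20	28	46	15	12	45	39	16	8	8
g070	7	7	6	7	1	6	3	5	5	2	5	8	4	2	5	7	4	3	7	11
g071	2	6	6	6	1	3	9	3	3	2	6	2	5	2	5	5	7	2	6	1
g072	31	34	40	27	35	32	34	29	48	49	19	28	30	27	34	28	34	51	39	30
g073	80	46	59	73	30	106	221	173	123	138	103	19	40	224	68	101	64	93	59	25
g074	1388	1901	1057	967	1500	969	1026	2174	977	726	1736	2116	2030	1444	951	1044	1781	990	1442	1887
g075	4	5	4	10	6	5	4	8	4	3	6	1	7	3	3	4	7	9	3	3
g076	484	624	717	584	527	584	513	564	699	604	561	564	381	471	615	527	684	562	641	462
g077	60	61	49	120	161	62	91	154	73	84	71	76	114	138	85	177	80	106	96	117
g078	253	297	238	278	245	205	241	259	243	273	269	232	223	225	314	258	224	208	208	245
g079	9	0	15	4	6	12	7	14	12	8	15	12	12	11	6	16	8	19	7	6
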