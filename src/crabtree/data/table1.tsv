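species	y_collection	cbs	other	ethanol_yield	biomass_yield	glc_cons_rate	etoh_prod_rate	growth_rate
Sac. weihenstephan A2	Y1288		34/70	0.52	0.17	1.44	0.75	0.232
Sac. weihenstephan A1	Y1288		34/70	0.50	0.17	1.62	0.84	0.222
Sac. cerevisiae A2	Y706	8340	CEN.PK113-7D	0.38	0.15	2.17	0.81	0.289
Sac. cerevisiae A1	Y706	8340	CEN.PK113-7D	0.39	0.16	1.84	0.71	0.271
Sac. Paradoxus	Y052	432	NRRLY-17217	0.45	0.17	1.79	0.81	0.338
Sac. Mikatae	Y393	8839	IFO1815	0.37	0.19	2.90	1.12	0.374
Sac. Uvarum	Y1124		CECT12600	0.43	0.17	1.96	0.80	0.281
Sac. eubayanus	Y1693	12357		0.40	0.17	2.00	0.82	0.324
Kaz. servazzii	Y055	4311	NRRLY-12661	0.33	0.07	0.62	0.19	0.036
Kaz. lodderae A2	Y489	2757	NRRLY-8280	0.31	0.16	1.87	0.62	0.303
Kaz. lodderae A1	Y489	2757	NRRLY-8280	0.34	0.16	1.75	0.60	0.281
Kaz. exiguus	Y670	1514	NRRLY-1538	0.43	0.43	0.18	1.75	0.740
Kaz. barnettii	Y477		NRRLY-27223	0.36	0.15	1.56	0.56	0.234
Nau. castellii A2	Y056	4309	NRRLY-27223	0.36	0.10	1.83	0.66	0.187
Nau. castellii A1	Y056	4309	NRRLY-27223	0.36	0.09	1.58	0.56	0.147
Nak. glabrata A2	Y475	138	NRRLY-1417	0.40	0.15	0.95	0.37	0.152
Nak. glabrata A1	Y475	138	NRRLY-1417	0.36	0.16	0.88	0.33	0.145
Nak. delphensis	476	2170	NRRLY-2379	0.39	0.11	1.87	0.72	0.202
Nak. bacillisporus	Y483	7720	UWOPS85-349.2	0.32	0.23	0.89	0.27	0.203
Nak. castellii A2	Y484	4332	NRRLY-17070	0.16	0.34	0.46	0.09	0.140
Nak. castellii A1	Y484	4332	NRRLY-17070	0.18	0.31	0.52	0.09	0.159
Tet. blattae A2	Y481	6284	NRRLY-10934	0.22	0.16	0.92	0.18	0.140
Tet. blattae A1	Y481	6284	NRRLY-10934	0.24	0.17	0.91	0.19	0.141
Tet. phaffii	Y482	4417	NRRLY-8282	0.38	0.12	0.89	0.31	0.099
Tet. iriomotensis A2	Y1299	8762	IFO10929	0.25	0.23	1.09	0.26	0.265
Tet. iriomotensis A1	Y1299	8762	IFO10929	0.26	0.24	1.21	0.33	0.284
Van. polysporus A2	Y1293	2163	NRRLY-8283	0.41	0.14	1.90	0.79	0.261
Van. polysporus A1	Y1293	2163	NRRLY-8283	0.41	0.13	1.84	0.73	0.258
Van. yarrowii	1677		NRRLY-17763	0.36	0.18	1.38	0.51	0.252
Zsa. rouxii A2	Y111	732	NRRLY-229	0.04	0.51	0.30	0.01	0.150
Zsa. rouxii A1	Y111	732	NRRLY-229	0.04	0.51	0.29	0.01	0.147
Zsa. bisporus	Y062	702	NRRLY-12626	0.16	0.31	0.49	0.06	0.153
Zto. florentinus A2	Y479	746	NRRLY-1560	0.35	0.21	1.35	0.51	0.276
Zto. florentinus A1	Y479	746	NRRLY-1560	0.37	0.22	1.35	0.48	0.275
Zto. mrakii	Y480	4218	NRRLY-12654	0.31	0.18	0.97	0.30	0.171
Tor. franciscae A2	Y1055	2926	NRRLY-6686	0.22	0.22	0.27	0.95	0.200
Tor. franciscae A1	Y1055	2926	NRRLY-6686	0.20	0.20	0.25	1.03	0.210
Lac. fermentati	Y083	4506	NRRLY-7434	0.31	0.23	1.41	0.45	0.300
Lac. thermotolerans	Y688	6340	NRRLY-8284	0.30	0.23	1.06	0.32	0.229
Lac. waltii A2	Y1062	6430	NRRLY-8285	0.19	0.25	0.87	0.15	0.245
Lac. waltii A1	Y1062	6430	NRRLY-8285	0.20	0.28	1.14	0.21	0.325
Lac. kluyverii B2	Y1651		UWOPS79-150	0.16	0.27	1.15	0.18	0.315
Lac. kluyverii B1	Y1651		UWOPS79-150	0.26	0.27	1.18	0.36	0.322
Lac. kluyverii A2	Y057	3082	NRRLY-12651	0.20	0.26	1.09	0.24	0.278
Lac. kluyverii A1	Y057	3082	NRRLY-12651	0.20	0.26	1.03	0.20	0.271
Klu. aestuarii	Y797	4438	NRRLYB-4510	0.00	0.49	0.66	0.00	0.429
Klu. nonfermentans	Y1057	8778	JCM10232	0.00	0.48	0.22	0.00	0.101
Klu. wickerhamii	Y113	2745	UCD54-210	0.00	0.50	0.63	0.00	0.321
Klu. lactis A2	Y707	2359	NRRLY-1140	0.00	0.57	0.48	0.00	0.255
Klu. lactis A1	Y707	2359	NRRLY-1140	0.00	0.56	0.57	0.00	0.341
Klu. marxianus C	Y1674	397		0.00	0.54	0.67	0.00	0.358
Klu. marxianus B	Y1675	2762	NCYC-970	0.00	0.49	0.54	0.00	0.269
Klu. marxianus A2	Y1058	712	NRRLY-8281	0.00	0.57	0.55	0.00	0.316
Klu. marxianus A1	Y1058	712	NRRLY-8281	0.00	0.56	0.54	0.00	0.314
Klu. dobzhanskii A2	Y796	2104	NRRLY-1974	0.13	0.38	0.75	0.09	0.279
Klu. dobzhanskii A1	Y796	2104	NRRLY-1974	0.16	0.36	0.80	0.13	0.271
Ere. coryli A2	Y999	2608	NRRLY-12970	0.12	0.70	0.25	0.03	0.158
Ere. coryli A1	Y999	2608	NRRLY-12970	0.11	0.65	0.25	0.03	0.151
Ere. sinecaudum A2	Y1002	8199	NRRLY-17231	0.00	0.44	0.28	0.00	0.117
Ere. sinecaudum A1	Y1002	8199	NRRLY-17231	0.00	0.44	0.29	0.00	0.122
Deb. vanrijiae A2	Y060	3024	NRRLY-7430	0.00	0.64	0.64	0.00	0.409
Deb. vanrijiae A1	Y060	3024	NRRLY-7430	0.00	0.64	0.57	0.00	0.347
Dek. bruxellensis	Y881	2796		0.26	0.23	0.64	0.17	0.147
Pic. philogaea	Y074	6696	NRRLY-7813	0.00	0.61	0.42	0.00	0.249
Pic. pastoris	Y1294			0.00	0.50	0.52	0.02	0.268
Sch. pombe	Y709		Eg282	0.35	0.15	0.82	0.28	0.122
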