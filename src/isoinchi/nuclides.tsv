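symbol	mass_number	exact_mass	abundance	stable
H	1	1.00782503207	0.999885	1
H	2	2.01410177812	0.000115	1
H	3	3.01604927790	0.0	0
B	10	10.01293695	0.199	1
B	11	11.00930536	0.801	1
C	12	12.0000000	0.9893	1
C	13	13.00335483507	0.0107	1
C	14	14.003241988	0.0	0
N	14	14.00307400443	0.99636	1
N	15	15.00010889888	0.00364	1
O	16	15.99491461957	0.99757	1
O	17	16.99913175650	0.00038	1
O	18	17.99915961286	0.00205	1
F	19	18.99840316273	1.0	1
Na	23	22.98976928196	1.0	1
Mg	24	23.985041697	0.7899	1
Mg	25	24.985836976	0.1000	1
Mg	26	25.982592968	0.1101	1
Si	28	27.97692653465	0.92223	1
Si	29	28.97649466490	0.04685	1
Si	30	29.973770136	0.03092	1
P	31	30.97376199842	1.0	1
S	32	31.97207117440	0.9499	1
S	33	32.97145890980	0.0075	1
S	34	33.96786700400	0.0425	1
S	36	35.96708071000	0.0001	1
Cl	35	34.968852682	0.7576	1
Cl	37	36.965902602	0.2424	1
K	39	38.96370648640	0.932581	1
K	40	39.96399816600	0.000117	1
K	41	40.96182525790	0.067302	1
Ca	40	39.962590863	0.96941	1
Ca	42	41.95861783	0.00647	1
Ca	43	42.95876644	0.00135	1
Ca	44	43.95548156	0.02086	1
Ca	46	45.9536890	0.00004	1
Ca	48	47.95252276	0.00187	1
Fe	54	53.93960899	0.05845	1
Fe	56	55.93493633	0.91754	1
Fe	57	56.93539284	0.02119	1
Fe	58	57.93327443	0.00282	1
Cu	63	62.92959772	0.6915	1
Cu	65	64.92786970	0.3085	1
Zn	64	63.92914201	0.4917	1
Zn	66	65.92603381	0.2773	1
Zn	67	66.92712775	0.0404	1
Zn	68	67.92484455	0.1845	1
Zn	70	69.92531920	0.0061	1
Se	74	73.922475934	0.0089	1
Se	76	75.919213704	0.0937	1
Se	77	76.919914154	0.0763	1
Se	78	77.917309280	0.2377	1
Se	80	79.916521800	0.4961	1
Se	82	81.916699500	0.0873	1
Br	79	78.918337600	0.5069	1
Br	81	80.916289700	0.4931	1
I	127	126.904471900	1.0	1
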