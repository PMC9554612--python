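name	chr	position_cM	ci_95	flanking_markers	n_qtls	avg_lod	avg_pve
MQTL1A.1	1A	108.15	1.5	RAC875_c34888_65/Excalibur_c48152_563	3	4.50	9.23
MQTL1A.2	1A	128.94	3.35	Excalibur_c20777_428/BS00110358_51	7	4.34	9.78
MQTL1A.3	1A	168.63	6.03	Tdurum_contig98378_452/IWB12795	2	5.21	7.10
MQTL1B.1	1B	162.82	4.94	BS00091126_51/Tdurum_contig9811_127	5	4.80	8.44
MQTL1B.2	1B	175.82	2.65	Kukri_c83200_268/BS00067003_51	2	4.15	7.65
MQTL1B.3	1B	188.02	4.35	Excalibur_c3510_159/BS00067290_51	3	4.43	11.00
MQTL1B.4	1B	245.16	12.07	Ex_c67582_735/IWB69702	2	4.05	8.30
MQTL2A.1	2A	31.12	4.14	BS00019744_51/GENE-1397_630	7	5.90	9.77
MQTL2A.2	2A	169.53	11.01	IAAV8700/Kukri_c31508_91	3	3.25	6.75
MQTL2A.3	2A	214.17	7.14	wsnp_Ex_rep_c103167_88182254	2	5.63	7.93
MQTL2B.1	2B	41.78	2.17	BS00061187_51/GENE-0559_171	3	4.99	16.31
MQTL2B.2	2B	106.73	0.68	Ku_c63748_1270/RAC875_rep_c110344_370	3	3.07	7.23
MQTL2B.3	2B	124.23	3.06	wsnp_Ex_c34303_42642389/BobWhite_c12911_788	7	5.48	9.28
MQTL2B.4	2B	164.06	4.86	RFL_Contig1445_1192/Kukri_c46361_295	3	5.60	6.20
MQTL2B.5	2B	217.06	0.46	IWB56961/Excalibur_c42364_134	5	5.38	7.32
MQTL2D.1	2D	77.9	0.47	wsnp_Ex_c1508_2881921/Excalibur_c18353_55	7	3.53	17.55
MQTL2D.2	2D	84.48	3.72	RFL_Contig2460_547/RAC875_rep_c105150_589	6	5.33	10.78
MQTL2D.3	2D	118.76	2.93	BS00067584_51/BS00009458_51	4	6.40	7.67
MQTL3A.1	3A	64	1.3	BobWhite_rep_c49374_348/TA003589-0518	2	3.90	11.50
MQTL3A.2	3A	168.01	8.56	wsnp_BE497169B_Ta_2_1/Excalibur_rep_c68267_309	13	8.89	15.10
MQTL3A.3	3A	241.52	7.44	BobWhite_c13210_115/Tdurum_contig86206_149	2	3.00	9.78
MQTL3B.1	3B	105.2	5.26	RAC875_c5966_1854/CAP7_c1576_371	7	5.44	18.03
MQTL3B.2	3B	151.5	2.01	IWB40683/IWB985	4	4.63	13.48
MQTL3B.3	3B	180.64	2.85	RAC875_c5799_170/BS00065934_51	2	4.30	3.80
MQTL3D.1	3D	113.92	3.61	RAC875_c22095_1545/IAAV5635	4	4.05	10.41
MQTL3D.2	3D	218.61	6.23	Xcdo407/AX-111337684	4	3.82	7.34
MQTL4A.1	4A	73.83	0.6	Tdurum_contig12696_528/BS00003914_51	3	5.39	20.47
MQTL4A.2	4A	144.99	2.68	IWB47937/AX-89398002	5	4.84	15.06
MQTL4B.1	4B	51.09	5.48	Tdurum_contig5427_314/Xwmc8	2	6.22	9.00
MQTL4B.2	4B	59.32	0.3	wPt-1046/SBG_21726/IWB8981	2	6.50	8.64
MQTL4B.3	4B	88.44	0.83	4B_s49916/Xcnl7	6	6.82	10.13
MQTL4B.4	4B	141.55	1.83	IWB1224/IWB3229	2	4.65	9.91
MQTL5A.1	5A	175.42	0.71	RAC875_c106584_1077/wsnp_Ex_c43642_49901192	2	5.23	6.97
MQTL5A.2	5A	190.16	2.26	BS00021708_51/Excalibur_c34426_723	4	6.67	12.96
MQTL5A.3	5A	234.54	6.27	Tdurum_contig42203_4222/CAP8_c2014_192	4	3.43	7.64
MQTL5A.4	5A	313.52	8.4	GENE-3344_224/Xwmc805	2	4.40	10.73
MQTL5B.1	5B	71.52	17.71	IWB8032/wsnp_BE497820B_Ta_2_1	2	3.50	11.45
MQTL5B.2	5B	109.96	4.1	IWB45714/Xbarc308	7	3.66	7.09
MQTL5B.3	5B	177.64	1.52	IWB8195/IWB29437	2	4.10	7.55
MQTL5D.1	5D	62.98	5.39	Xwmc289/Xwmc434	2	3.40	8.85
MQTL6A.1	6A	212.49	9.58	Jagger_c8913_220/RAC875_c104548_369	2	5.94	20.00
MQTL6B.1	6B	66.45	2.45	wsnp_RFL_Contig2223_1603535/Tdurum_contig10149_284	5	3.02	9.98
MQTL6B.2	6B	101.67	2.46	IWB7667/IWB22499	2	18.40	9.65
MQTL6B.3	6B	134.02	14.14	IWA4745/Kukri_c20894_1233	2	3.70	4.10
MQTL6D.1	6D	44.81	0.3	Excalibur_c1991_1504/RAC875_rep_c85994_258	2	3.00	5.78
MQTL6D.2	6D	96.95	9.69	RAC875_c37031_312/D_contig17879_55	2	7.25	12.55
MQTL7A.1	7A	6.51	5.11	Excalibur_c34115_727/Excalibur_c57160_208	2	5.85	11.35
MQTL7A.2	7A	153.85	2.97	Ra_c54443_444/Excalibur_c44734_935	10	4.89	8.88
MQTL7A.3	7A	162	1.93	RAC875_c4336_208/BS00010282_51	2	8.07	5.01
MQTL7A.4	7A	167.62	3.03	wsnp_Ra_c63822_63288359/Excalibur_c34807_431	9	3.51	6.21
MQTL7A.5	7A	171.91	0.58	Xbarc222/Ra_c9427_300	2	8.96	11.91
MQTL7A.6	7A	205.68	3.48	IWB35185/IWB59328	2	2.98	7.27
MQTL7A.7	7A	256.45	2.45	IWB35275/IWB39743	4	6.23	4.50
MQTL7B.1	7B	58.74	2.64	Excalibur_c17927_284/BS00064146_51	5	6.71	4.85
MQTL7B.2	7B	71.42	10.22	Excalibur_c15405_808/Xgwm400/IWB36802	2	6.00	17.45
MQTL7B.3	7B	202.42	6.33	BobWhite_c44404_312/Excalibur_c18228_286	2	4.82	8.65
MQTL7D.1	7D	96.95	9.7	Xbarc214/Xgwm130	2	2.80	21.34
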