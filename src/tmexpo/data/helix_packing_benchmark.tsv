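# Published benchmark: 73 transmembrane helices from 14 alpha-helical membrane
# proteins (15 chains) used in a helical-packing study, with observed
# rotational angles from the structures, angles predicted from the rASA
# moment, the printed per-helix angular errors, per-chain MAAE (degrees,
# parenthesized in the source table) and predicted-rASA moment lengths.
# Angles in degrees [0, 360); printed values are rounded to 0.01.
pdb_chain	chain_maae	helix	sequence	observed	predicted	error	moment_length
1BL8:A	30.86	1	HWRAAGAATVLLVIVLLAGSYLAVLA	199.55	203.38	3.83	1.46
1BL8:A	30.86	2	WGRCVAVVVMVAGITSFGLVTAALAT	240.88	298.78	57.90	1.87
1C3W:A	42.28	1	IWLALGTALMGLGTLYFLVKGMG	318.98	355.18	36.19	3.38
1C3W:A	42.28	2	KFYAITTLVPAIAFTMYLSMLL	262.69	313.32	50.63	2.74
1C3W:A	42.28	3	WARYADWLFTTPLLLLDLALL	118.84	44.89	73.95	1.60
1C3W:A	42.28	4	GTILALVGADGIMIGTGLVGAL	357.99	332.94	25.05	2.80
1C3W:A	42.28	5	RFVWWAISTAAMLYILYVLFFGF	154.03	169.74	15.71	2.25
1C3W:A	42.28	6	FKVLRNVTVVLWSAYPVVWLIG	133.56	164.23	30.67	2.70
1C3W:A	42.28	7	ETLLFMVLDVSAKVGFGLILLRS	214.98	278.73	63.75	1.93
1OKC:A	65.78	1	LSFLKDFLAGGVAAAISKTAVAPIER	24.46	46.33	21.87	1.59
1OKC:A	65.78	2	NLANVIRYFPTQALNFAFKDKYKQIFL	207.77	114.64	93.14	1.75
1OKC:A	65.78	3	WRYFAGNLASGGAAGATSLCFVYPLDFART	112.40	70.30	42.09	1.32
1OKC:A	65.78	4	YQGFNVSVQGIIIYRAAYFGVYDTAKGMLP	179.94	59.44	120.50	1.40
1OKC:A	65.78	5	HIIVSWMIAQTVTAVAGLVSYPFDTVRR	264.34	315.20	50.85	0.98
1OKC:A	65.78	6	AWSNVLRGMGGAFVLVLYDEI	172.16	105.90	66.25	1.87
1ORS:C	62.09	1	VELGVSYAALLSVIVVVVEYTMQL	268.82	191.51	77.31	0.70
1ORS:C	62.09	2	LVRLYLVDLILVIILWADYAY	167.76	133.29	34.46	1.71
1ORS:C	62.09	3	KKTLYEIPALVPAGLLALIE	27.58	321.07	66.51	0.72
1ORS:C	62.09	4	LVRLLRFLRILLIISRGSKFLSAIA	233.80	303.87	70.07	0.62
2B6O:A	33.01	1	RAIFAEFFATLFYVFFGLGAS	308.42	335.32	26.90	1.44
2B6O:A	33.01	2	LQVALAFGLALATLVQAVGHIS	59.48	65.56	6.07	1.17
2B6O:A	33.01	3	LRAICYVVAQLLGAVAGAAVLYSV	354.70	13.71	19.01	2.35
2B6O:A	33.01	4	GQATIVEIFLTLQFVLCIFATY	61.06	71.11	10.05	1.58
2B6O:A	33.01	5	GSVALAVGFSLTLGHLFGM	342.15	109.29	127.14	1.21
2B6O:A	33.01	6	WVYWVGPVIGAGLGSLLYDFLL	49.77	58.65	8.88	1.58
2BL2:A	41.83	1	VLAMATATIFSGIGSAKGVG	45.15	105.31	60.16	0.99
2BL2:A	41.83	2	LPGTQGLYGFVIAFLIFI	285.84	259.80	26.04	1.70
2BL2:A	41.83	3	LGASLPIAFTGLFSGIAQ	82.57	87.25	4.68	1.39
2BL2:A	41.83	4	MVETYAILGFVISFLLVL	7.10	290.64	76.46	1.13
2BS2:C	51.33	1	WQSATGLFLGLFMIGHMFFVST	285.17	308.25	23.08	1.79
2BS2:C	51.33	2	IVVSFLAAFVFAVFIAHAFLAMR	55.33	17.57	37.76	2.89
2BS2:C	51.33	3	LWWIQAMTGFAMFFLGSVHLYIMMTQP	188.56	222.27	33.71	1.48
2BS2:C	51.33	4	WMWPLYLVLLFAVELHGSVGLYRLAV	192.12	322.45	130.33	1.38
2BS2:C	51.33	5	RANLKKLKTLMSAFLIVLGLLTFGAYV	185.58	153.82	31.76	3.30
2H88:C	45.70	1	HRGTGVALSLGVSLFSLAALLLP	123.28	203.88	80.60	1.69
2H88:C	45.70	2	LIYSAKFALVFPLSYHTWNGIR	307.08	253.07	54.01	0.39
2H88:C	45.70	3	VVVLILTLLSSAAIASE	74.04	71.55	2.50	2.05
2H88:D	27.22	1	VSALLLGLLPAAYLYPG	229.60	234.10	4.50	1.06
2H88:D	27.22	2	AVDYSLAAALTLHGHWGL	8.24	354.67	13.57	0.95
2H88:D	27.22	3	GLYVLSAITFTGLCYFNYYDV	334.89	271.30	63.59	1.49
2OAR:A	113.71	1	VAVVIGTAFTALVTKFTDSIITPLINRIG	319.36	203.39	115.96	0.37
2OAR:A	113.71	2	TIDLNVLLSAAINFFLIAFAVYFL	105.75	354.30	111.46	1.06
2QTS:A	11.07	1	VWALCFMGSLALLALVCTNRIQ	285.04	280.66	4.38	2.32
2QTS:A	11.07	2	AGLLGDIGGQMGLFIGASILTVL	41.15	23.39	17.76	2.22
2RH1:A	35.73	1	WVVGMGIVMSLIVLAIVFGNVLVITAIA	253.60	259.99	6.39	1.71
2RH1:A	35.73	2	YFITSLACADLVMGLAVVPFGAAHIL	293.99	341.90	47.91	1.06
2RH1:A	35.73	3	WCEFWTSIDVLCVTASIETLCVIAV	279.34	285.10	5.77	0.68
2RH1:A	35.73	4	RVIILMVWIVSGLTSFLPIQMHWYR	88.76	102.09	13.33	1.93
2RH1:A	35.73	5	FTNQAYAIASSIVSFYVPLVIMVFVYS	158.19	84.71	73.47	1.88
2RH1:A	35.73	6	LGIIMGTFTLCWLPFFIVNIVHVIQ	106.50	159.31	52.82	1.40
2RH1:A	35.73	7	IRKEVYILLNWIGYVNSGFNPLIYC	271.42	321.81	50.39	1.50
2UUH:A	10.47	1	AAVTLLGVLLQAYF	60.17	77.84	17.67	1.38
2UUH:A	10.47	2	SEYFPLFLATLWVAG	96.55	80.38	16.17	0.77
2UUH:A	10.47	3	AALCGLVYLFARLR	191.79	197.96	6.17	2.39
2UUH:A	10.47	4	LYASARALWLLVALAAL	116.59	118.45	1.86	2.57
2Z73:A	35.30	1	SLGIFIGICGIIGCGGNGIVIY	276.78	317.73	40.94	3.01
2Z73:A	35.30	2	FIINLAFSDFTFSLVNGFPLMTI	206.68	252.82	46.14	1.12
2Z73:A	35.30	3	VYGFIGGIFGFMSIMTMAMISI	303.09	339.23	36.14	0.80
2Z73:A	35.30	4	FIMIIFVWLWSVLWAIGPIF	99.36	72.24	27.11	2.67
2Z73:A	35.30	5	NILCMFILGFFGPILIIFFCYF	270.54	293.89	23.35	2.49
2Z73:A	35.30	6	SIVIVSQFLLSWSPYAVVAL	127.57	154.75	27.18	2.12
2Z73:A	35.30	7	QLPVMFAKASAIHNPMIYSV	60.63	106.85	46.22	2.01
3B9W:A	33.25	1	YSINILAMLLVGFGFLMV	232.00	229.10	2.90	0.63
3B9W:A	33.25	2	ATTGTYLVVATGLPLYILL	193.50	227.23	33.73	0.87
3B9W:A	33.25	3	IYAEFAVATGLIAMGAVL	221.13	199.82	21.31	0.05
3B9W:A	33.25	4	FQYALLALFIVPVYLLNE	11.39	35.81	24.42	1.15
3B9W:A	33.25	5	GSIAIHAFGAYFGLGVSIA	208.92	309.21	100.29	0.73
3B9W:A	33.25	6	FSMLGSMVLWLFWPSFA	284.14	287.41	3.27	1.16
3B9W:A	33.25	7	VNTLLALCGATLATYFLSAL	36.54	3.47	33.07	1.57
3B9W:A	33.25	8	VDMANAALAGGVAIGSVC	138.00	55.95	82.05	0.24
3B9W:A	33.25	9	VGAFVIGLLGGAISVVGF	11.05	21.65	10.60	1.90
3B9W:A	33.25	10	TCGVHNLHGLPGLLGGFSAIL	112.57	156.18	43.61	0.92
3B9W:A	33.25	11	LTGIGITLALALIGGVIAGALIKLT	103.20	92.65	10.55	2.58
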