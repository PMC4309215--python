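gene_symbol	gene_group	campaign	condition	mean_fi	sd	n
ALB	reference	PFC	H/W	42.13	2.04	3
ALB	reference	PFC	1g	40.28	1.22	3
ALB	reference	PFC	1.8g	40.62	0.88	3
ALB	reference	PFC	ug	40.1	0.71	3
B4GALT6	reference	PFC	H/W	40.55	7.65	3
B4GALT6	reference	PFC	1g	39.3	7.62	3
B4GALT6	reference	PFC	1.8g	43.41	11.38	3
B4GALT6	reference	PFC	ug	39.92	7.62	3
GAPDH	reference	PFC	H/W	21791.23	914.23	3
GAPDH	reference	PFC	1g	21162.32	1447.99	3
GAPDH	reference	PFC	1.8g	19124.58	1319.5	3
GAPDH	reference	PFC	ug	20823.21	2005.0	3
HMBS	reference	PFC	H/W	2184.2	973.77	3
HMBS	reference	PFC	1g	1612.83	677.49	3
HMBS	reference	PFC	1.8g	998.73	443.39	3
HMBS	reference	PFC	ug	1226.98	531.59	3
RPLP0	reference	PFC	H/W	11352.34	1728.26	5
RPLP0	reference	PFC	1g	11633.77	426.19	5
RPLP0	reference	PFC	1.8g	11380.89	2060.5	5
RPLP0	reference	PFC	ug	12714.95	837.1	5
TBP	reference	PFC	H/W	4158.56	310.25	3
TBP	reference	PFC	1g	3271.43	217.26	3
TBP	reference	PFC	1.8g	2287.2	161.09	3
TBP	reference	PFC	ug	2776.82	170.76	3
YWHAZ	reference	PFC	H/W	9136.31	2070.39	7
YWHAZ	reference	PFC	1g	9445.22	1990.27	7
YWHAZ	reference	PFC	1.8g	9843.3	2125.25	7
YWHAZ	reference	PFC	ug	9853.06	2184.44	7
ABCC1	abc	PFC	H/W	3140.46	751.71	3
ABCC1	abc	PFC	1g	3309.29	743.99	3
ABCC1	abc	PFC	1.8g	2258.45	325.89	3
ABCC1	abc	PFC	ug	2934.79	496.93	3
ABCC4	abc	PFC	H/W	1497.37	199.75	3
ABCC4	abc	PFC	1g	1437.84	279.45	3
ABCC4	abc	PFC	1.8g	857.05	30.65	3
ABCC4	abc	PFC	ug	1067.01	91.26	3
ABCD4	abc	PFC	H/W	1719.37	164.62	4
ABCD4	abc	PFC	1g	1254.13	240.26	4
ABCD4	abc	PFC	1.8g	765.94	235.75	4
ABCD4	abc	PFC	ug	1155.89	257.53	4
ABCF2	abc	PFC	H/W	7510.96	664.99	3
ABCF2	abc	PFC	1g	6774.22	407.85	3
ABCF2	abc	PFC	1.8g	6022.09	525.91	3
ABCF2	abc	PFC	ug	6525.51	515.17	3
TAP2	abc	PFC	H/W	3365.61	136.24	3
TAP2	abc	PFC	1g	2614.83	94.54	3
TAP2	abc	PFC	1.8g	2485.22	190.87	3
TAP2	abc	PFC	ug	2027.84	74.61	3
ALB	reference	TEXUS	H/W	18.02	1.29	3
ALB	reference	TEXUS	BL	17.47	1.18	3
ALB	reference	TEXUS	ug	17.88	1.88	3
B4GALT6	reference	TEXUS	H/W	17.15	4.26	3
B4GALT6	reference	TEXUS	BL	17.67	6.05	3
B4GALT6	reference	TEXUS	ug	15.95	3.26	3
GAPDH	reference	TEXUS	H/W	23385.82	1721.78	3
GAPDH	reference	TEXUS	BL	24862.07	2271.02	3
GAPDH	reference	TEXUS	ug	25451.17	1692.9	3
HMBS	reference	TEXUS	H/W	2921.4	1084.02	3
HMBS	reference	TEXUS	BL	3087.49	1094.22	3
HMBS	reference	TEXUS	ug	2568.23	899.65	3
RPLP0	reference	TEXUS	H/W	8027.1	1233.45	5
RPLP0	reference	TEXUS	BL	9036.11	1538.2	5
RPLP0	reference	TEXUS	ug	7406.41	2622.46	5
TBP	reference	TEXUS	H/W	3738.25	143.9	3
TBP	reference	TEXUS	BL	4466.01	257.59	3
TBP	reference	TEXUS	ug	3517.69	53.87	3
YWHAZ	reference	TEXUS	H/W	3970.64	1498.1	7
YWHAZ	reference	TEXUS	BL	5738.74	2118.2	7
YWHAZ	reference	TEXUS	ug	3776.01	1596.71	7
ABCC1	abc	TEXUS	H/W	2405.02	686.83	3
ABCC1	abc	TEXUS	BL	3096.07	634.6	3
ABCC1	abc	TEXUS	ug	2020.76	398.49	3
ABCC4	abc	TEXUS	H/W	765.34	293.67	3
ABCC4	abc	TEXUS	BL	1382.37	294.64	3
ABCC4	abc	TEXUS	ug	537.87	140.92	3
ABCD4	abc	TEXUS	H/W	759.92	190.32	4
ABCD4	abc	TEXUS	BL	843.89	94.39	4
ABCD4	abc	TEXUS	ug	565.11	138.98	4
ABCF2	abc	TEXUS	H/W	8382.41	751.1	3
ABCF2	abc	TEXUS	BL	7963.43	721.46	3
ABCF2	abc	TEXUS	ug	6373.22	573.28	3
TAP2	abc	TEXUS	H/W	4902.84	12.08	3
TAP2	abc	TEXUS	BL	4000.89	35.26	3
TAP2	abc	TEXUS	ug	3430.97	49.27	3
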