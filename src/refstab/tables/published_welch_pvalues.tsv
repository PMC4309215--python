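gene_symbol	campaign	condition_a	condition_b	p_published
ALB	PFC	H/W	1g	0.2627
ALB	PFC	1g	1.8g	0.7154
ALB	PFC	1.8g	ug	0.4724
ALB	PFC	1g	ug	0.8383
B4GALT6	PFC	H/W	1g	0.8506
B4GALT6	PFC	1g	1.8g	0.6342
B4GALT6	PFC	1.8g	ug	0.6847
B4GALT6	PFC	1g	ug	0.9253
GAPDH	PFC	H/W	1g	0.5652
GAPDH	PFC	1g	1.8g	0.1466
GAPDH	PFC	1.8g	ug	0.2971
GAPDH	PFC	1g	ug	0.825
HMBS	PFC	H/W	1g	0.4563
HMBS	PFC	1g	1.8g	0.2695
HMBS	PFC	1.8g	ug	0.5994
HMBS	PFC	1g	ug	0.4833
RPLP0	PFC	H/W	1g	0.7397
RPLP0	PFC	1g	1.8g	0.8004
RPLP0	PFC	1.8g	ug	0.2346
RPLP0	PFC	1g	ug	0.0425
TBP	PFC	H/W	1g	0.0192
TBP	PFC	1g	1.8g	0.0042
TBP	PFC	1.8g	ug	0.0226
TBP	PFC	1g	ug	0.039
YWHAZ	PFC	H/W	1g	0.7808
YWHAZ	PFC	1g	1.8g	0.7239
YWHAZ	PFC	1.8g	ug	0.9934
YWHAZ	PFC	1g	ug	0.7214
ABCC1	PFC	H/W	1g	0.7959
ABCC1	PFC	1g	1.8g	0.1193
ABCC1	PFC	1.8g	ug	0.1312
ABCC1	PFC	1g	ug	0.5141
ABCC4	PFC	H/W	1g	0.7805
ABCC4	PFC	1g	1.8g	0.0676
ABCC4	PFC	1.8g	ug	0.0459
ABCC4	PFC	1g	ug	0.138
ABCD4	PFC	H/W	1g	0.0222
ABCD4	PFC	1g	1.8g	0.0273
ABCD4	PFC	1.8g	ug	0.0673
ABCD4	PFC	1g	ug	0.5972
ABCF2	PFC	H/W	1g	0.1916
ABCF2	PFC	1g	1.8g	0.1263
ABCF2	PFC	1.8g	ug	0.3019
ABCF2	PFC	1g	ug	0.5496
TAP2	PFC	H/W	1g	0.0023
TAP2	PFC	1g	1.8g	0.3711
TAP2	PFC	1.8g	ug	0.0394
TAP2	PFC	1g	ug	0.0014
ALB	TEXUS	H/W	BL	0.6184
ALB	TEXUS	BL	ug	0.7708
ALB	TEXUS	H/W	ug	0.9215
B4GALT6	TEXUS	H/W	BL	0.9093
B4GALT6	TEXUS	BL	ug	0.6933
B4GALT6	TEXUS	H/W	ug	0.7197
GAPDH	TEXUS	H/W	BL	0.4238
GAPDH	TEXUS	BL	ug	0.7383
GAPDH	TEXUS	H/W	ug	0.2126
HMBS	TEXUS	H/W	BL	0.8609
HMBS	TEXUS	BL	ug	0.5612
HMBS	TEXUS	H/W	ug	0.6872
RPLP0	TEXUS	H/W	BL	0.2871
RPLP0	TEXUS	BL	ug	0.2728
RPLP0	TEXUS	H/W	ug	0.6499
TBP	TEXUS	H/W	BL	0.0215
TBP	TEXUS	BL	ug	0.0201
TBP	TEXUS	H/W	ug	0.1037
YWHAZ	TEXUS	H/W	BL	0.0993
YWHAZ	TEXUS	BL	ug	0.0758
YWHAZ	TEXUS	H/W	ug	0.818
ABCC1	TEXUS	H/W	BL	0.2701
ABCC1	TEXUS	BL	ug	0.0797
ABCC1	TEXUS	H/W	ug	0.4598
ABCC4	TEXUS	H/W	BL	0.062
ABCC4	TEXUS	BL	ug	0.0228
ABCC4	TEXUS	H/W	ug	0.3164
ABCD4	TEXUS	H/W	BL	0.4697
ABCD4	TEXUS	BL	ug	0.0194
ABCD4	TEXUS	H/W	ug	0.1539
ABCF2	TEXUS	H/W	BL	0.5244
ABCF2	TEXUS	BL	ug	0.043
ABCF2	TEXUS	H/W	ug	0.0238
TAP2	TEXUS	H/W	BL	0.0001
TAP2	TEXUS	BL	ug	0.0002
TAP2	TEXUS	H/W	ug	0.0002
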