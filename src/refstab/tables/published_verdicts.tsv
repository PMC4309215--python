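gene_symbol	campaign	condition_a	condition_b	verdict
ALB	PFC	H/W	1g	+
ALB	PFC	1g	1.8g	+
ALB	PFC	1.8g	ug	+
ALB	PFC	1g	ug	+
ALB	TEXUS	H/W	BL	+
ALB	TEXUS	BL	ug	+
ALB	TEXUS	H/W	ug	+
B4GALT6	PFC	H/W	1g	+
B4GALT6	PFC	1g	1.8g	+
B4GALT6	PFC	1.8g	ug	+
B4GALT6	PFC	1g	ug	+
B4GALT6	TEXUS	H/W	BL	+
B4GALT6	TEXUS	BL	ug	+
B4GALT6	TEXUS	H/W	ug	+
GAPDH	PFC	H/W	1g	+
GAPDH	PFC	1g	1.8g	+
GAPDH	PFC	1.8g	ug	+
GAPDH	PFC	1g	ug	+
GAPDH	TEXUS	H/W	BL	+
GAPDH	TEXUS	BL	ug	+
GAPDH	TEXUS	H/W	ug	+
HMBS	PFC	H/W	1g	+
HMBS	PFC	1g	1.8g	+
HMBS	PFC	1.8g	ug	+
HMBS	PFC	1g	ug	+
HMBS	TEXUS	H/W	BL	+
HMBS	TEXUS	BL	ug	+
HMBS	TEXUS	H/W	ug	+
RPLP0	PFC	H/W	1g	+
RPLP0	PFC	1g	1.8g	+
RPLP0	PFC	1.8g	ug	+
RPLP0	PFC	1g	ug	-
RPLP0	TEXUS	H/W	BL	+
RPLP0	TEXUS	BL	ug	+
RPLP0	TEXUS	H/W	ug	+
TBP	PFC	H/W	1g	-
TBP	PFC	1g	1.8g	-
TBP	PFC	1.8g	ug	-
TBP	PFC	1g	ug	-
TBP	TEXUS	H/W	BL	-
TBP	TEXUS	BL	ug	-
TBP	TEXUS	H/W	ug	+
YWHAZ	PFC	H/W	1g	+
YWHAZ	PFC	1g	1.8g	+
YWHAZ	PFC	1.8g	ug	+
YWHAZ	PFC	1g	ug	+
YWHAZ	TEXUS	H/W	BL	+
YWHAZ	TEXUS	BL	ug	+
YWHAZ	TEXUS	H/W	ug	+
ABCA5	PFC	H/W	1g	+
ABCA5	PFC	1g	1.8g	+
ABCA5	PFC	1.8g	ug	+
ABCA5	PFC	1g	ug	+
ABCA5	TEXUS	H/W	BL	+
ABCA5	TEXUS	BL	ug	+
ABCA5	TEXUS	H/W	ug	+
ABCA9	PFC	H/W	1g	+
ABCA9	PFC	1g	1.8g	+
ABCA9	PFC	1.8g	ug	+
ABCA9	PFC	1g	ug	+
ABCA9	TEXUS	H/W	BL	+
ABCA9	TEXUS	BL	ug	+
ABCA9	TEXUS	H/W	ug	+
ABCC1	PFC	H/W	1g	+
ABCC1	PFC	1g	1.8g	+
ABCC1	PFC	1.8g	ug	+
ABCC1	PFC	1g	ug	+
ABCC1	TEXUS	H/W	BL	+
ABCC1	TEXUS	BL	ug	+
ABCC1	TEXUS	H/W	ug	+
ABCC4	PFC	H/W	1g	+
ABCC4	PFC	1g	1.8g	+
ABCC4	PFC	1.8g	ug	-
ABCC4	PFC	1g	ug	+
ABCC4	TEXUS	H/W	BL	+
ABCC4	TEXUS	BL	ug	-
ABCC4	TEXUS	H/W	ug	+
ABCC12	PFC	H/W	1g	-
ABCC12	PFC	1g	1.8g	+
ABCC12	PFC	1.8g	ug	+
ABCC12	PFC	1g	ug	+
ABCC12	TEXUS	H/W	BL	-
ABCC12	TEXUS	BL	ug	-
ABCC12	TEXUS	H/W	ug	+
ABCD4	PFC	H/W	1g	-
ABCD4	PFC	1g	1.8g	-
ABCD4	PFC	1.8g	ug	+
ABCD4	PFC	1g	ug	+
ABCD4	TEXUS	H/W	BL	+
ABCD4	TEXUS	BL	ug	-
ABCD4	TEXUS	H/W	ug	+
ABCF2	PFC	H/W	1g	+
ABCF2	PFC	1g	1.8g	+
ABCF2	PFC	1.8g	ug	+
ABCF2	PFC	1g	ug	+
ABCF2	TEXUS	H/W	BL	+
ABCF2	TEXUS	BL	ug	-
ABCF2	TEXUS	H/W	ug	-
TAP2	PFC	H/W	1g	-
TAP2	PFC	1g	1.8g	+
TAP2	PFC	1.8g	ug	-
TAP2	PFC	1g	ug	-
TAP2	TEXUS	H/W	BL	-
TAP2	TEXUS	BL	ug	-
TAP2	TEXUS	H/W	ug	-
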