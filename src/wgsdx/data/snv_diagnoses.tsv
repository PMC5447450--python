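case_id	sex	locus_id	gene	moi	variant	zygosity	origin	category	partial
1004	F	EP300	EP300	AD	c.5723dupC	het	NA	1	no
1006	M	MC4R	MC4R	AD	c.751A>C	het	maternal	2	yes
1008	M	SMARCB1	SMARCB1	AD	c.364del	het	NA	1	no
1009	M	LARP7	LARP7	AR	c.756_757del	hom	maternal+paternal	2	no
1012	M	KAT6B	KAT6B	AD	c.3021+1G>C	het	de_novo	1	no
1015	M	GDF5	GDF5	AD	c.847G>A	het	de_novo	2	no
1016	F	PANK2	PANK2	AR	c.824_825del	hom	maternal+paternal	2	no
1023	F	NGLY1	NGLY1	AR	c.1201A>T	hom	maternal+paternal	2	no
1029	F	PIK3R2	PIK3R2	AD	c.1117G>A	het	de_novo	2	no
1032	F	SPTAN1	SPTAN1	AD	c.6947A>C	het	de_novo	1	no
1040	M	EXT2	EXT2	AD	c.1760C>T	het	NA	1	yes
1045	M	TSEN54	TSEN54	AR	c.919G>T	hom	maternal+paternal	1	no
1049	F	NSD1	NSD1	AD	c.3922-1G>C	het	NA	1	no
1050	M	CBL	CBL	AD	c.1096-11_1109del	het	de_novo	1	no
1055	F	PACS1	PACS1	AD	c.607C>T	het	de_novo	2	no
1057	F	SETD5	SETD5	AD	c.1576_1580del	het	de_novo	2	no
1059	M	PIK3R1	PIK3R1	AD	c.1993G>A	het	paternal	1	no
1062	M	GJB2	GJB2	AR	c.35delG	hom	maternal+paternal	1	yes
1066	M	CCM2	CCM2	AD	c.1054delG	het	paternal	1	no
1070	F	VWF	VWF	AD	c.6187C>T	hom	maternal+paternal	1	yes
1078	M	TYR	TYR	AR	c.1118C>A/c.1205G>A	het/het	maternal+paternal	1	no
1078	M	MC4R	MC4R	AD	c.307G>A	het	NA	2	no
1080	M	COL4A1	COL4A1	AD	c.2317G>A	het	de_novo	1	no
1089	M	PLVAP	PLVAP	AR	c.1072C>T	hom	maternal+paternal	3	no
1093	F	NGLY1	NGLY1	AR	c.517A>G	hom	maternal+paternal	2	no
1093	F	COG5	COG5	AR	c.1205C>T	hom	maternal+paternal	1	no
1102	M	ATP1A3	ATP1A3	AD	c.2452G>A	het	de_novo	1	no
1103	F	VPS53	VPS53	AR	c.1429C>T/c.1716T>G	het/het	maternal+paternal	2	no
1107	F	SMARCA2	SMARCA2	AD	c.2639C>T	het	de_novo	1	no
1108	F	ALDH18A1	ALDH18A1	AR	c.1321C>T/c.191G>A	het/het	maternal+paternal	2	no
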