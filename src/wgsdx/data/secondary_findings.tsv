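case_id	sex	gene	inheritance	variant	zygosity	condition	also_primary
1003	F	FBN1	AD	c.3509G>A	het	Marfan syndrome	no
1027	F	COL3A1	AD	c.812G>A	het	Ehlers-Danlos syndrome type III/IV	yes
1040	M	SCN5A	AD/AR	c.5239G>A	het	Brugada syndrome 1 and related cardiac conditions	yes
1063	F	KCNH2	AD	c.3278C>T	het	Long QT syndrome / Short QT syndrome	no
1067	M	SCN5A	AD/AR	c.5336C>T	het	Brugada syndrome 1 and related cardiac conditions	no
1078	M	RYR2	AD	c.3320C>T	het	Arrhythmogenic right ventricular dysplasia 2	yes
1091	M	DSG2	AD	c.2434G>A	het	Arrhythmogenic right ventricular dysplasia 10	no
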