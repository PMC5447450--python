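case_id	sex	locus_id	region	size_kb	state	origin	category	partial
1090	F	chrX_turner	ChrX:60701-91873056	91813	loss	de_novo	1	yes
1090	F	chrX_turner	ChrX:91877172-155174078	63297	gain	de_novo	1	yes
1005	M	4p16.3	Chr4:33574-7608090	7575	loss	de_novo	1	no
1034	F	22q11.2	Chr22:18713432-21440515	2727	loss	de_novo	1	no
1022	F	10p11.23	Chr10:30822400-32872626	2050	loss	de_novo	2	no
1026	M	22q12.3	Chr22:35931002-37272620	1342	loss	NA	3	no
1066	M	8q22.1	Chr8:97145564-98301541	1156	loss	de_novo	2	no
1027	F	16p13.11	Chr16:15507164-16400833	894	loss	de_novo	2	no
1102	M	2p16.3_NRXN1	Chr2:51021507-51358841	337	loss	de_novo	2	no
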