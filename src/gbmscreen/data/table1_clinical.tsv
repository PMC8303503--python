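sample_id	sex	age_at_diagnosis	kps	who_grade	recurrent_tumor	os_months	idh1_r132h	atrx_loss	p53	mgmt_methylation	gtr	therapy	adjuvant_therapy	ttp_months
NB-00131/12	M	42	90	IV	No	13	Negative	Not performed	Negative	No	No	60 Gy radiotherapy + TMZ	Adjuvant TMZ	/
NB-00094/13	M	47	90	IV	No	16	Negative	Not performed	Positive	Yes	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	10
17-H-21518	M	64	100	IV	No	16	Negative	No	Negative	No	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	8
NB-00233/12	F	42	100	IV	No	18	Negative	Not performed	Negative	No	Yes	60 Gy radiotherapy + TMZ	No (TMZ side effects)	6
NB-00464/12	M	62	90	IV	No	19	Not performed	Not performed	Not performed	No	No	30 Gy radiotherapy + TMZ	Adjuvant TMZ	14
NB-00079/14	M	43	90	IV	No	20	Positive	Not performed	Positive	No	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	15
17-H-05191	M	68	100	IV	No	21	Negative	No	Positive	No	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	12
16-H-17976	M	66	70	IV	No	23	Negative	No	Negative	Yes	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	16
NB-00173/14	M	55	90	IV	No	26	Negative	Not performed	Negative	Yes	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	21
NB-00369/13	F	62	90	IV	No	31	Negative	Not performed	Positive	No	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	26
NB-00450/12	F	58	80	IV	No	50	Negative	Not performed	Negative	Yes	No	60 Gy radiotherapy + TMZ	Adjuvant TMZ	37
NB-00038/13	F	61	80	IV	No	58	Negative	Not performed	Positive	No	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	14
NB-00339/13	M	22	100	IV	No	91	Negative	Not performed	Negative	No	Yes	60 Gy radiotherapy + TMZ	Adjuvant TMZ	90 *
NB-00046/12	M	62	80	IV	No	2	Negative	Not performed	Negative	Yes	No	34 Gy radiotherapy + TMZ	No	2
NB-00003/15	F	68	70	IV	No	2	Negative	Yes	Negative	No	No	30 Gy radiotherapy	/	2
17-H-31914	M	70	50	IV	No	2	Negative	No	Negative	Yes	No	None	None	2
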