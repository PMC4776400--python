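patient	age_years	education_years	handedness	time_post_onset	lesion_volume_ul	pct_left_cortex_damaged
P1	47	18	Right	4y 1m	34032	5.07
P2	67	21	Right	15y 5m	169128	22.53
P3	70	24	Right	1y	4904
P4	75	15	Right	2y 4m	34440	4.20
P5	79	10	Right	2y 1m	37896	4.80
P6	46	15	Right	2y 3m	33904	4.84
P7	62	16	Right	1y 2m	53456	6.92
P8	84	19	Right	10y	3176
P9	73	19	Left	5y 8m	27440	4.09
P10	77	20	Right	7m	23648	2.81
P11	66	20	Right	5y 3m	78616	9.59
P12	58	14	Right	1y 1m	148904	19.32
P13	46	16	Right	4y	101584	12.71
P14	57	12	Right	2y	146160	20.31
P15	65	20	Right	6y 1m	158936	21.96
P16	68	13	Right	3y 3m	22152	3.24
P17	60	14	Right	8y 8m	103896	14.89
P18	69	15	Right	1y	9104	0.0013
P19	68	14	Right	4y 7m	54192	6.67
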