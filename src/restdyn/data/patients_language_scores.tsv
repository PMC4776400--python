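patient	bnt	ppvt	navs_sct_can	navs_sct_noncan	navs_sppt_can	navs_sppt_noncan	palpa9	wab_fluency	wab_comprehension	wab_repetition	wab_object_naming	wab_aphasia_score	wab_language_score
P1	8	118	93.33	93.33	20	26.67	NT	5	8	7.5	9.5	78.3	75
P2	NT	93	73.33	40.00	NT	NT	NT	NT	NT	NT	NT	NT	NT
P3	4	100	100	100	100	100	100	10	10	10	10	96.7	95
P4	2	105	100	73.33	66.67	53.33	98.75	8	10	7.5	7.5	80	77.5
P5	17	121	100	100	100	100	NT	8	10	9.5	10	95.8	91.9
P6	5	100	100	73.33	60	33.33	93.75	8	9	7.5	10	90.83	86.87
P7	3	90	80	40.00	NT	NT	NT	6	8	4	8	62	62.5
P8	6	98	100	100.00	86.67	80	NT	9	9	10	9.5	94.17	89.37
P9	8	122	80	66.67	93.33	86.67	NT	9	10	10	10	98.3	97.5
P10	1	0	60	53.33	NT	NT	66.25	7	9	6	6	62	51
P11	9	118	66.67	73.33	40	20	NT	9	10	9	10	97	96
P12	1	93	80	86.67	33.33	6.67	81.25	2	10	5	2	45	38.75
P13	5	101	100	100	100	93.33	98.75	6	10	9.5	10	52.5	70.5
P14	1	74	80	46.67	NT	NT	92.5	2	8	6	7	58.3	48.75
P15	1	87	53.33	80	NT	NT	NT	0	7	3.5	0.5	25	22.5
P16	10	98	100	60	100	100	97.5	9	9	10	10	95	96.25
P17	3	91	100	60	73.33	20	98.75	8	9	7	10	86.7	85
P18	2	94	86.67	86.67	40.00	40.00	88.75	4	9	9	9	75	66.88
P19	8	99	93.33	100.00	93.33	53.33	100	8	10	8.5	10	90.8	86.9
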