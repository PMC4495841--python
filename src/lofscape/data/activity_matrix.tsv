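allele	MPP+	TEA+	ASP+	morphine	metformin	tropisetron	O-desmethyltramadol	debrisoquine	tyramine	monocrotaline
*1	100	100	100	100	100	100	100	100	100	100
*2	95	40	70	45	25	10	15	95	30	0
*3	20	15	10	20	10	15	10	25	10	5
*4	10	5	0	15	5	10	5	28	5	0
*5	2	1	0	1	0	0	1	2	0	0
*6	1	2	1	0	1	0	0	3	1	0
*7	95	30	92	20	10	25	30	98	0	10
*8	110	165	105	170	160	120	110	105	115	175
*9	100	105	98	168	102	95	100	98	105	100
*10	92	10	85	15	5	10	10	95	0	20
*11	96	25	91	30	15	20	25	94	0	15
*12	0	1	0	2	0	1	0	2	0	0
*13	91	30	60	25	10	20	30	85	5	25
*14	15	10	5	20	8	12	10	30	5	5
*15	2	0	1	0	1	0	0	1	0	0
*1A	105	100	98	102	100	97	101	99	103	100
*2A	94	42	68	48	26	11	14	96	28	0
*7A	96	32	90	22	11	24	31	97	0	9
*7B	93	28	94	18	9	26	29	99	0	11
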