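population	*1	*2	*3	*4	*5	*6	*7	*8	*9	*10	*11	*12	*13	*14	*15	*16
San	91.7	0	0	0	0	0	0	8.3	0	0	0	0	0	0	0	0
Mbuti Pygmy	76.9	7.7	0	0	0	0	0	15.4	0	0	0	0	0	0	0	0
Biaka Pygmy	76.9	11.5	0	0	0	0	9.6	1.9	0	0	0	0	0	0	0	0
Bantu S.W.	87.5	6.3	0	0	0	0	6.3	0	0	0	0	0	0	0	0	0
Bantu N.E.	63.6	9.1	0	0	0	0	9.1	18.2	0	0	0	0	0	0	0	0
Bantu (LWK-1K)	88.1	4.1	0	0	0	0	2.6	5.1	0	0	0	0	0	0	0	0
Mandenka	90.9	4.6	0	0	0	0	2.3	2.3	0	0	0	0	0	0	0	0
Yoruba	95.5	0	0	0	0	0	2.3	2.3	0	0	0	0	0	0	0	0
Yoruba (YRI-1K)	90.3	2.3	0	0	0	0	1.7	5.7	0	0	0	0	0	0	0	0
Mozabite	82.8	12.1	0	1.72	0	1.72	1.72	0	0	0	0	0	0	0	0	0
Bedouin	72.8	9.8	10.9	0	3.26	0	2.17	1.1	0	0	0	0	0	0	0	0
Palestinian	78.9	13.3	3.33	0	0	2.22	2.22	0	0	0	0	0	0	0	0	0
Druze	77.4	17.9	4.76	0	0	0	0	0	0	0	0	0	0	0	0	0
Tuscan	87.5	12.5	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Tuscan (TSI-1K)	71.9	18.9	5.6	2.55	0.51	0	0	0.5	0	0.5	0	0	0	0	0	0
Sardinian	69.6	21.4	1.8	5.36	0	1.79	0	0	0	0	0	0	0	0	0	0
North Italian	89.3	7.14	3.6	0	0	0	0	0	0	0	0	0	0	0	0	0
Iberian (IBS-1K)	75.0	14.3	3.6	7.14	0	0	0	0	0	0	0	0	0	0	0	0
French Basque	72.9	18.8	4.2	4.17	0	0	0	0	0	0	0	0	0	0	0	0
French	62.5	21.4	7.14	1.79	5.36	1.79	0	0	0	0	0	0	0	0	0	0
British (GBR-1K)	72.5	16.3	5.06	2.25	3.37	0.56	0	0	0	0	0	0	0	0	0	0
Orcadian	80.0	13.3	6.67	0	0	0	0	0	0	0	0	0	0	0	0	0
German	71.4	15.8	8.12	2.14	2.56	0	0	0	0	0	0	0	0	0	0	0
Finn (FIN-1K)	78.5	13.4	5.38	1.61	1.08	0	0	0	0	0	0	0	0	0	0	0
Adygei	70.6	17.6	5.88	0	2.94	0	0	0	0	2.94	0	0	0	0	0	0
Russian	66.0	10.0	10.0	6.0	8.0	0	0	0	0	0	0	0	0	0	0	0
Balochi	66.7	27.1	6.25	0	0	0	0	4.2	0	0	0	0	0	0	0	0
Brahui	62.0	26.0	6.0	0	6.0	0	0	0	0	0	0	0	0	2.0	0	0
Makrani	84.0	16.0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Sindhi	83.3	12.5	0	0	0	0	4.17	0	0	0	0	0	0	0	0	0
Pathan	72.0	26.0	2.0	0	0	0	0	0	0	0	0	0	0	0	0	0
Kalash	73.9	19.6	6.52	0	0	0	0	0	0	0	0	0	2.17	0	0	0
Burusho	84.0	6.0	6.0	0	4.0	0	0	0	0	0	0	0	0	0	0	0
Hazara	89.1	4.35	2.17	0	0	2.17	0	0	0	0	0	0	2.17	0	0	0
Uygur	80.0	15.0	5.0	0	0	0	0	0	0	0	0	0	0	0	0	0
Yakut	92.0	0	4.0	0	0	0	0	0	4.0	0	0	0	0	0	0	0
Dai	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
She	90.0	0	0	0	0	0	0	0	0	0	0	10.0	0	0	0	0
Tujia	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Yizu	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Naxi	94.4	0	0	0	0	0	0	0	0	0	5.56	0	0	0	0	0
Tu	90.0	0	0	0	0	0	0	0	0	0	0	0	0	0	5.0	5.0
Xibo	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Mongola	85.0	10.0	0	0	0	0	0	0	5.0	0	0	0	0	0	0	0
Hezhen	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Daur	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Oroqen	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Han	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Han Beijing (CHB-1K)	98.5	0.52	0	0	0	0	0	0	0.52	0	0.52	0	0	0	0	0
Han South (CHS-1K)	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Lahu	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Miaozu	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Cambodian	95.0	5.0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Japanese	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Japanese (JPT-1K)	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Melanesian	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Papuan	100	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Colombian	57.1	42.9	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Karitiana	39.3	60.7	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Maya	66.7	33.3	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Pima	82.1	17.9	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Surui	6.25	93.8	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Colombian (CLM-1K)	65.8	29.2	3.33	0.83	0.83	0	0	0	0	0	0	0	0	0	0	0
Mexican (MXL-1K)	59.1	32.6	4.55	0	3.03	0	0.76	0	0	0	0	0	0	0	0	0
Puerto Rican (PUR-1K)	76.4	20.0	0.91	0	1.82	0	0	0	0	0.91	0	0	0	0	0	0
Caucasians (CEU-1K)	72.4	15.3	8.82	1.76	1.18	0.59	0	0	0	0	0	0	0	0	0	0
Africans (ASW-1K)	87.7	8.2	0	1.64	0.82	0	0	0.82	0	0	0	0	0	0	0	0.82
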