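population	region	n_individuals	admixed	source
San	Sub-Saharan Africa	6	0	HGDP
Mbuti Pygmy	Sub-Saharan Africa	13	0	HGDP
Biaka Pygmy	Sub-Saharan Africa	26	0	HGDP
Bantu S.W.	Sub-Saharan Africa	8	0	HGDP
Bantu N.E.	Sub-Saharan Africa	11	0	HGDP
Bantu (LWK-1K)	Sub-Saharan Africa	97	0	1KG
Mandenka	Sub-Saharan Africa	22	0	HGDP
Yoruba	Sub-Saharan Africa	22	0	HGDP
Yoruba (YRI-1K)	Sub-Saharan Africa	88	0	1KG
Mozabite	North Africa and Middle East	29	0	HGDP
Bedouin	North Africa and Middle East	46	0	HGDP
Palestinian	North Africa and Middle East	45	0	HGDP
Druze	North Africa and Middle East	42	0	HGDP
Tuscan	Europe	8	0	HGDP
Tuscan (TSI-1K)	Europe	98	0	1KG
Sardinian	Europe	28	0	HGDP
North Italian	Europe	14	0	HGDP
Iberian (IBS-1K)	Europe	14	0	1KG
French Basque	Europe	24	0	HGDP
French	Europe	28	0	HGDP
British (GBR-1K)	Europe	89	0	1KG
Orcadian	Europe	15	0	HGDP
German	Europe	117	0	HGDP
Finn (FIN-1K)	Europe	93	0	1KG
Adygei	Europe	17	0	HGDP
Russian	Europe	25	0	HGDP
Balochi	Central Asia	24	0	HGDP
Brahui	Central Asia	25	0	HGDP
Makrani	Central Asia	25	0	HGDP
Sindhi	Central Asia	24	0	HGDP
Pathan	Central Asia	25	0	HGDP
Kalash	Central Asia	23	0	HGDP
Burusho	Central Asia	25	0	HGDP
Hazara	Central Asia	23	0	HGDP
Uygur	Central Asia	10	0	HGDP
Yakut	Central Asia	25	0	HGDP
Dai	East Asia and Oceania	10	0	HGDP
She	East Asia and Oceania	10	0	HGDP
Tujia	East Asia and Oceania	10	0	HGDP
Yizu	East Asia and Oceania	10	0	HGDP
Naxi	East Asia and Oceania	9	0	HGDP
Tu	East Asia and Oceania	10	0	HGDP
Xibo	East Asia and Oceania	9	0	HGDP
Mongola	East Asia and Oceania	10	0	HGDP
Hezhen	East Asia and Oceania	9	0	HGDP
Daur	East Asia and Oceania	10	0	HGDP
Oroqen	East Asia and Oceania	9	0	HGDP
Han	East Asia and Oceania	45	0	HGDP
Han Beijing (CHB-1K)	East Asia and Oceania	97	0	1KG
Han South (CHS-1K)	East Asia and Oceania	100	0	1KG
Lahu	East Asia and Oceania	8	0	HGDP
Miaozu	East Asia and Oceania	10	0	HGDP
Cambodian	East Asia and Oceania	10	0	HGDP
Japanese	East Asia and Oceania	30	0	HGDP
Japanese (JPT-1K)	East Asia and Oceania	89	0	1KG
Melanesian	East Asia and Oceania	14	0	HGDP
Papuan	East Asia and Oceania	17	0	HGDP
Colombian	America	7	0	HGDP
Karitiana	America	14	0	HGDP
Maya	America	21	0	HGDP
Pima	America	14	0	HGDP
Surui	America	8	0	HGDP
Colombian (CLM-1K)	Admixed	60	1	1KG
Mexican (MXL-1K)	Admixed	66	1	1KG
Puerto Rican (PUR-1K)	Admixed	55	1	1KG
Caucasians (CEU-1K)	Admixed	85	1	1KG
Africans (ASW-1K)	Admixed	61	1	1KG
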