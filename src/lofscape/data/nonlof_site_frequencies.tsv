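population	Met408Val	Pro341Leu	Arg342His	Phe160Leu	Gly414Ala
San	0.26	0.03	0.12	0.02	0.0
Mbuti Pygmy	0.26	0.03	0.12	0.02	0.0
Biaka Pygmy	0.26	0.03	0.12	0.02	0.0
Bantu S.W.	0.26	0.03	0.12	0.02	0.0
Bantu N.E.	0.26	0.03	0.12	0.02	0.0
Bantu (LWK-1K)	0.26	0.03	0.12	0.02	0.0
Mandenka	0.26	0.03	0.12	0.02	0.0
Yoruba	0.26	0.03	0.12	0.02	0.0
Yoruba (YRI-1K)	0.26	0.03	0.12	0.02	0.0
Mozabite	0.3	0.04	0.03	0.03	0.0
Bedouin	0.3	0.04	0.03	0.03	0.0
Palestinian	0.3	0.04	0.03	0.03	0.0
Druze	0.3	0.04	0.03	0.03	0.0
Tuscan	0.4	0.06	0.0	0.05	0.01
Tuscan (TSI-1K)	0.4	0.06	0.0	0.05	0.01
Sardinian	0.4	0.06	0.0	0.05	0.01
North Italian	0.4	0.06	0.0	0.05	0.01
Iberian (IBS-1K)	0.4	0.06	0.0	0.05	0.01
French Basque	0.4	0.06	0.0	0.05	0.01
French	0.4	0.06	0.0	0.05	0.01
British (GBR-1K)	0.4	0.06	0.0	0.05	0.01
Orcadian	0.4	0.06	0.0	0.05	0.01
German	0.4	0.06	0.0	0.05	0.01
Finn (FIN-1K)	0.4	0.06	0.0	0.05	0.01
Adygei	0.4	0.06	0.0	0.05	0.01
Russian	0.4	0.06	0.0	0.05	0.01
Balochi	0.35	0.1	0.01	0.04	0.0
Brahui	0.35	0.1	0.01	0.04	0.0
Makrani	0.35	0.1	0.01	0.04	0.0
Sindhi	0.35	0.1	0.01	0.04	0.0
Pathan	0.35	0.1	0.01	0.04	0.0
Kalash	0.35	0.1	0.01	0.04	0.0
Burusho	0.35	0.1	0.01	0.04	0.0
Hazara	0.35	0.1	0.01	0.04	0.0
Uygur	0.35	0.1	0.01	0.04	0.0
Yakut	0.35	0.1	0.01	0.04	0.0
Dai	0.25	0.16	0.0	0.03	0.0
She	0.25	0.16	0.0	0.03	0.0
Tujia	0.25	0.16	0.0	0.03	0.0
Yizu	0.25	0.16	0.0	0.03	0.0
Naxi	0.25	0.16	0.0	0.03	0.0
Tu	0.25	0.16	0.0	0.03	0.0
Xibo	0.25	0.16	0.0	0.03	0.0
Mongola	0.25	0.16	0.0	0.03	0.0
Hezhen	0.25	0.16	0.0	0.03	0.0
Daur	0.25	0.16	0.0	0.03	0.0
Oroqen	0.25	0.16	0.0	0.03	0.0
Han	0.25	0.16	0.0	0.03	0.0
Han Beijing (CHB-1K)	0.25	0.16	0.0	0.03	0.0
Han South (CHS-1K)	0.25	0.16	0.0	0.03	0.0
Lahu	0.25	0.16	0.0	0.03	0.0
Miaozu	0.25	0.16	0.0	0.03	0.0
Cambodian	0.25	0.16	0.0	0.03	0.0
Japanese	0.25	0.16	0.0	0.03	0.0
Japanese (JPT-1K)	0.25	0.16	0.0	0.03	0.0
Melanesian	0.25	0.16	0.0	0.03	0.0
Papuan	0.25	0.16	0.0	0.03	0.0
Colombian	0.08	0.0	0.0	0.0	0.0
Karitiana	0.08	0.0	0.0	0.0	0.0
Maya	0.08	0.0	0.0	0.0	0.0
Pima	0.08	0.0	0.0	0.0	0.0
Surui	0.08	0.0	0.0	0.0	0.0
Colombian (CLM-1K)	0.3	0.05	0.02	0.03	0.005
Mexican (MXL-1K)	0.3	0.05	0.02	0.03	0.005
Puerto Rican (PUR-1K)	0.3	0.05	0.02	0.03	0.005
Caucasians (CEU-1K)	0.3	0.05	0.02	0.03	0.005
Africans (ASW-1K)	0.3	0.05	0.02	0.03	0.005
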