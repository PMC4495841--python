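allele	variants	parent	category	composition_known
*1		-	reference	1
*2	Met420del	-	major	1
*3	Arg61Cys	-	major	1
*4	Gly401Ser	-	major	1
*5	Gly465Arg,Met420del	-	major	1
*6	Cys88Arg,Met420del	-	major	1
*7	Ser14Phe	-	major	1
*8	Arg488Met	-	major	1
*9	Pro117Leu	-	major	1
*10	Ser189Leu	-	major	1
*11	Ile449Thr	-	major	1
*12	Ser29Leu	-	major	1
*13	Thr245Met	-	major	1
*14	Arg206Cys,Met420del	-	major	1
*15	Glu284Lys	-	major	1
*16		-	major	0
*1A	Met408Val	*1	sub	1
*1B	Phe160Leu	*1	sub	1
*1C	Pro341Leu	*1	sub	1
*1D	Arg342His	*1	sub	1
*1E	Gly414Ala	*1	sub	1
*1F	Met408Val,Pro341Leu	*1	sub	1
*2A	Met420del,Met408Val	*2	sub	1
*2B	Met420del,Pro341Leu	*2	sub	1
*3A	Arg61Cys,Met408Val	*3	sub	1
*4A	Gly401Ser,Met408Val	*4	sub	1
*7A	Ser14Phe,Met408Val	*7	sub	1
*7B	Ser14Phe,Arg342His	*7	sub	1
*8A	Arg488Met,Met408Val	*8	sub	1
*13A	Thr245Met,Met408Val	*13	sub	1
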