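variant_id	codon	ref_residue	alt_residue	rs_id	functional_class
Ser14Phe	14	S	F	rs34447885	LOF
Ser29Leu	29	S	L		LOF
Arg61Cys	61	R	C	rs12208357	LOF
Cys88Arg	88	C	R	rs55918055	LOF
Gln97Lys	97	Q	K		unknown
Pro117Leu	117	P	L		non_LOF
Phe160Leu	160	F	L	rs683369	non_LOF
Ser189Leu	189	S	L		LOF
Arg206Cys	206	R	C		LOF
Gly220Val	220	G	V		unknown
Thr245Met	245	T	M		LOF
Glu284Lys	284	E	K		LOF
Pro341Leu	341	P	L	rs2282143	non_LOF
Arg342His	342	R	H		non_LOF
Gly401Ser	401	G	S	rs34130495	LOF
Met408Val	408	M	V	rs628031	non_LOF
Gly414Ala	414	G	A		non_LOF
Met420del	420	M	del	rs72552763	LOF
Ile449Thr	449	I	T		LOF
Gly465Arg	465	G	R	rs34059508	LOF
Arg488Met	488	R	M	rs35270274	non_LOF
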