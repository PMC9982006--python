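substrate	role	exchange_id	in_vivo	in_silico_published	reference
D-glucose	carbon	EX_glc__D	+	+	B37
D-Fructose	carbon	EX_fru	+	+	B37
Raffinose	carbon	EX_raffin	+	+	B37
L-Arabinose	carbon	EX_arab__L	+	+	B37
Mannose	carbon	EX_man	+	+	B4
Lactose	carbon	EX_lcts	+	+	B4
Trehalose	carbon	EX_tre	+	+	B4
Melibiose	carbon	EX_melib	-	+	B4
Acetate	carbon	EX_ac	+	-	B4
Inositol	carbon	EX_inost	-	-	B22
Mannitol	carbon	EX_mnl	+	+	B22
L-Rhamnose	carbon	EX_rmn	+	+	B22
Sucrose	carbon	EX_sucr	+	+	B22
Xylitol	carbon	EX_xylt	+	+	B22
D-xylose	carbon	EX_xyl__D	+	+	B22
Citrate	carbon	EX_cit	+	+	B22
L-Arginine	carbon	EX_arg__L	+	+	B4
L-Alanine	carbon	EX_ala__L	+	+	B4
L-Aspartate	carbon	EX_asp__L	+	+	B4
Glycine	carbon	EX_gly	+	+	B4
L-Histidine	carbon	EX_his__L	-	+	B4
L-Lysine	carbon	EX_lys__L	+	+	B4
L-phenylalanine	carbon	EX_phe__L	+	+	B4
L-Tryptophan	carbon	EX_trp__L	+	-	B4
L-Methionine	carbon	EX_met__L	+	-	B4
L-Isoleucine	carbon	EX_ile__L	-	-	B4
L-Valine	carbon	EX_val__L	-	-	B4
L-Asparagine	carbon	EX_asn__L	-	-	B4
NH4+	nitrogen	EX_nh4	+	+	this_study
KNO3	nitrogen	EX_no3	+	+	this_study
Urea	nitrogen	EX_urea	+	+	this_study
L-Cysteine	nitrogen	EX_cys__L	+	-	B22
L-phenylalanine	nitrogen	EX_phe__L	+	+	B29
L-Threonine	nitrogen	EX_thr__L	+	+	B29
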