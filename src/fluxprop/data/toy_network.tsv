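# fluxprop toy CHO-like network
# biomass_reaction: biomass
# essential: arginine,cysteine,histidine,isoleucine,leucine,lysine,methionine,phenylalanine,threonine,tryptophan,valine
reaction_id	equation	lower_bound	upper_bound
EX_glucose	glucose <=>	-1000	1000
EX_lactate	lactate <=>	-1000	1000
EX_ammonium	ammonium <=>	-1000	1000
EX_alanine	alanine <=>	-1000	1000
EX_arginine	arginine <=>	-1000	1000
EX_asparagine	asparagine <=>	-1000	1000
EX_aspartate	aspartate <=>	-1000	1000
EX_cysteine	cysteine <=>	-1000	1000
EX_glutamate	glutamate <=>	-1000	1000
EX_glutamine	glutamine <=>	-1000	1000
EX_glycine	glycine <=>	-1000	1000
EX_histidine	histidine <=>	-1000	1000
EX_isoleucine	isoleucine <=>	-1000	1000
EX_leucine	leucine <=>	-1000	1000
EX_lysine	lysine <=>	-1000	1000
EX_methionine	methionine <=>	-1000	1000
EX_phenylalanine	phenylalanine <=>	-1000	1000
EX_proline	proline <=>	-1000	1000
EX_serine	serine <=>	-1000	1000
EX_threonine	threonine <=>	-1000	1000
EX_tryptophan	tryptophan <=>	-1000	1000
EX_tyrosine	tyrosine <=>	-1000	1000
EX_valine	valine <=>	-1000	1000
EX_co2	co2 <=>	0	1000
EX_urea	urea <=>	0	1000
biomass	0.6 alanine + 0.28 arginine + 0.35 asparagine + 0.35 aspartate + 0.1 cysteine + 0.5 glutamate + 0.35 glutamine + 0.55 glycine + 0.1 histidine + 0.25 isoleucine + 0.45 leucine + 0.4 lysine + 0.1 methionine + 0.2 phenylalanine + 0.3 proline + 0.4 serine + 0.3 threonine + 0.05 tryptophan + 0.15 tyrosine + 0.3 valine + 0.35 glucose -->	0	1000
glycolysis_lac	glucose --> 2 lactate	0	1000
glucose_oxidation	glucose --> 6 co2	0	1000
CAT_alanine	alanine --> ammonium + 2 co2	0	1000
SYN_alanine	glucose + ammonium --> alanine	0	1000
CAT_arginine	arginine --> ammonium + 2 co2	0	1000
CAT_asparagine	asparagine --> ammonium + 2 co2	0	1000
SYN_asparagine	glucose + ammonium --> asparagine	0	1000
CAT_aspartate	aspartate --> ammonium + 2 co2	0	1000
SYN_aspartate	glucose + ammonium --> aspartate	0	1000
CAT_cysteine	cysteine --> ammonium + 2 co2	0	1000
CAT_glutamate	glutamate --> ammonium + 2 co2	0	1000
SYN_glutamate	glucose + ammonium --> glutamate	0	1000
CAT_glutamine	glutamine --> ammonium + 2 co2	0	1000
SYN_glutamine	glucose + ammonium --> glutamine	0	1000
CAT_glycine	glycine --> ammonium + 2 co2	0	1000
SYN_glycine	glucose + ammonium --> glycine	0	1000
CAT_histidine	histidine --> ammonium + 2 co2	0	1000
CAT_isoleucine	isoleucine --> ammonium + 2 co2	0	1000
CAT_leucine	leucine --> ammonium + 2 co2	0	1000
CAT_lysine	lysine --> ammonium + 2 co2	0	1000
CAT_methionine	methionine --> ammonium + 2 co2	0	1000
CAT_phenylalanine	phenylalanine --> ammonium + 2 co2	0	1000
CAT_proline	proline --> ammonium + 2 co2	0	1000
SYN_proline	glucose + ammonium --> proline	0	1000
CAT_serine	serine --> ammonium + 2 co2	0	1000
SYN_serine	glucose + ammonium --> serine	0	1000
CAT_threonine	threonine --> ammonium + 2 co2	0	1000
CAT_tryptophan	tryptophan --> ammonium + 2 co2	0	1000
CAT_tyrosine	tyrosine --> ammonium + 2 co2	0	1000
SYN_tyrosine	glucose + ammonium --> tyrosine	0	1000
CAT_valine	valine --> ammonium + 2 co2	0	1000
urea_synthesis	2 ammonium + co2 --> urea	0	1000
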