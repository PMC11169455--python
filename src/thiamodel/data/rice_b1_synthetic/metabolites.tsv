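id	name	compartment	initial_conc_nmol_per_L	boundary
AIR_p	5-aminoimidazole ribonucleotide	plastid	10.0	0
SAM_p	S-adenosylmethionine	plastid	20.0	0
SAH_p	S-adenosylhomocysteine	plastid	10.0	0
NAD_p	NAD	plastid	40.0	0
GLY_p	glycine	plastid	100.0	0
ATP_p	ATP	plastid	1000000.0	0
ADP_p	ADP	plastid	10000.0	0
HMP_P_p	HMP-P	plastid	10.0	0
HMP_PP_p	HMP-PP	plastid	5.0	0
HET_P_p	HET-P	plastid	10.0	0
TMP_p	thiamin monophosphate	plastid	1.0	0
TMP_c	thiamin monophosphate	cytosol	1.0	0
THI_c	thiamin	cytosol	5.0	0
TDP_c	thiamin diphosphate	cytosol	50.0	0
ATP_c	ATP	cytosol	1000000.0	0
ADP_c	ADP	cytosol	10000.0	0
HET_c	hydroxyethylthiazole	cytosol	10.0	0
HET_P_c	HET-P	cytosol	2.0	0
PI_c	phosphate	cytosol	10.0	0
TMP_m	thiamin monophosphate	mitochondrion	0.5	0
THI_m	thiamin	mitochondrion	2.0	0
TDP_m	thiamin diphosphate	mitochondrion	100.0	0
PI_m	phosphate	mitochondrion	10.0	0
AIR_ext	AIR feed	external	500.0	1
SAM_ext	SAM feed	external	2000.0	1
GLY_ext	glycine feed	external	50000.0	1
NAD_ext	NAD feed	external	10000.0	1
HET_ext	thiazole salvage feed	external	50.0	1
TDP_ext	TDP sink	external	0.0	1
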