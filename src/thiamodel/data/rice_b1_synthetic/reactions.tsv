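id	enzyme	stoichiometry	law_type	vmax	km	km_a	km_b	k	substrates	reversible	needs_fba
t_air	transport	-1:AIR_ext,+1:AIR_p	mass_action					0.0001	AIR_ext	0	0
t_sam	transport	-1:SAM_ext,+1:SAM_p	mass_action					5e-05	SAM_ext	0	0
t_gly	transport	-1:GLY_ext,+1:GLY_p	mass_action					1e-05	GLY_ext	0	0
t_nad	transport	-1:NAD_ext,+1:NAD_p	mass_action					2e-05	NAD_ext	0	0
t_het	transport	-1:HET_ext,+1:HET_c								0	1
t_tmp_pc	transport	-1:TMP_p,+1:TMP_c	mass_action					0.01	TMP_p	0	0
t_tmp_cm	transport	-1:TMP_c,+1:TMP_m								0	1
t_thi_mc	transport	-1:THI_m,+1:THI_c	mass_action					0.005	THI_m	0	0
t_tdp_cm	TDP_carrier	-1:TDP_c,+1:TDP_m	mass_action					0.005	TDP_c	0	0
t_hetp_cp	transport	-1:HET_P_c,+1:HET_P_p								0	1
THIC	THIC	-1:AIR_p,-1:SAM_p,+1:HMP_P_p,+1:SAH_p	MM2	0.03		10.0	20.0		AIR_p;SAM_p	0	0
THI1	THI1	-1:NAD_p,-1:GLY_p,+1:HET_P_p	MM1	0.01	60.0				NAD_p	0	0
TH1_kinase	TH1	-1:HMP_P_p,-1:ATP_p,+1:HMP_PP_p,+1:ADP_p	MM2	0.4		8.0	200000.0		HMP_P_p;ATP_p	0	0
TH1_synthase	TH1	-1:HMP_PP_p,-1:HET_P_p,+1:TMP_p	MM2	0.3		10.0	10.0		HMP_PP_p;HET_P_p	0	0
THiM	THiM	-1:HET_c,-1:ATP_c,+1:HET_P_c,+1:ADP_c	MM2	0.02		20.0	200000.0		HET_c;ATP_c	0	0
TH2_c	TH2	-1:TMP_c,+1:THI_c,+1:PI_c	MM1	0.05	5.0				TMP_c	0	0
TH2_m	TH2	-1:TMP_m,+1:THI_m,+1:PI_m	MM1	0.02	5.0				TMP_m	0	0
TDPK	TDPK	-1:THI_c,-1:ATP_c,+1:TDP_c,+1:ADP_c	MM1	0.03	20.0				THI_c	0	0
atp_regen_p	ATP_regen	-1:ADP_p,+1:ATP_p	mass_action					0.001	ADP_p	0	0
atp_regen_c	ATP_regen	-1:ADP_c,+1:ATP_c	mass_action					0.001	ADP_c	0	0
sah_drain	methyl_cycle	-1:SAH_p	mass_action					0.01	SAH_p	0	0
tdp_export_c	transport	-1:TDP_c,+1:TDP_ext	mass_action					0.005	TDP_c	0	0
tdp_use_m	cofactor_use	-1:TDP_m	mass_action					0.001	TDP_m	0	0
thi_drain_c	degradation	-1:THI_c	mass_action					0.001	THI_c	0	0
sam_use_p	methylation_demand	-1:SAM_p	mass_action					0.005	SAM_p	0	0
t_tmp_cp	transport	-1:TMP_c,+1:TMP_p								0	1
t_thi_cm	transport	-1:THI_c,+1:THI_m	mass_action					0.001	THI_c	0	0
TDPase_c	TDPase	-1:TDP_c,+1:TMP_c	MM1	0.005	100.0				TDP_c	0	0
pi_export_c	transport	-1:PI_c	mass_action					0.001	PI_c	0	0
pi_export_m	transport	-1:PI_m	mass_action					0.001	PI_m	0	0
t_tdp_mc	transport	-1:TDP_m,+1:TDP_c								0	1
nad_use_p	NAD_use	-1:NAD_p	mass_action					0.005	NAD_p	0	0
gly_use_p	GLY_use	-1:GLY_p	mass_action					0.005	GLY_p	0	0
air_use_p	purine_branch	-1:AIR_p	mass_action					0.005	AIR_p	0	0
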