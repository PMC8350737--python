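id	equation	lb	ub	subsystem
glf_glc	glc_e -> glc_c	0	1000	transport
glf_xyl	xyl_e -> xyl_c	0	1000	transport
o2t	o2_e <-> o2_c	-1000	1000	transport
actnt	actn_c <-> actn_e	-1000	1000	transport
bdot	bdo_c <-> bdo_e	-1000	1000	transport
glyct	glyc_c -> glyc_e	0	1000	transport
co2t	co2_c <-> co2_e	-1000	1000	transport
h2ot	h2o_c <-> h2o_e	-1000	1000	transport
pit	pi_e <-> pi_c	-1000	1000	transport
etoht	etoh_c -> etoh_e	0	1000	transport
EX_glc_e	glc_e ->	-1000	0	exchange
EX_xyl_e	xyl_e ->	-1000	0	exchange
EX_o2_e	o2_e ->	-1000	0	exchange
EX_actn_e	actn_e ->	-1000	1000	exchange
EX_bdo_e	bdo_e ->	-1000	1000	exchange
EX_glyc_e	glyc_e ->	0	1000	exchange
EX_co2_e	co2_e ->	0	1000	exchange
EX_h2o_e	h2o_e ->	-1000	1000	exchange
EX_pi_e	pi_e ->	-1000	1000	exchange
EX_etoh_e	etoh_e ->	0	1000	exchange
EX_biomass	biomass ->	0	1000	exchange
glk	glc_c + atp_c -> g6p_c + adp_c	0	1000	ED
pgi	g6p_c <-> f6p_c	-1000	1000	EMP
g6pdh	g6p_c + nadp_c -> 6pgl_c + nadph_c	0	1000	ED
pgl	6pgl_c + h2o_c -> 6pg_c	0	1000	ED
gnd	6pg_c + nadp_c -> ru5p_c + co2_c + nadph_c	0	1000	PPP
edd	6pg_c -> kdpg_c + h2o_c	0	1000	ED
eda	kdpg_c -> pyr_c + gap_c	0	1000	ED
tpi	dhap_c <-> gap_c	-1000	1000	EMP
gapdh	gap_c + nad_c + pi_c <-> bpg_c + nadh_c	-1000	1000	EMP
pgk	bpg_c + adp_c <-> 3pg_c + atp_c	-1000	1000	EMP
pgm	3pg_c <-> 2pg_c	-1000	1000	EMP
eno	2pg_c <-> pep_c + h2o_c	-1000	1000	EMP
pyk	pep_c + adp_c -> pyr_c + atp_c	0	1000	EMP
xylA	xyl_c <-> xlu_c	-1000	1000	xylose
xylB	xlu_c + atp_c -> x5p_c + adp_c	0	1000	xylose
rpe	ru5p_c <-> x5p_c	-1000	1000	PPP
rpi	ru5p_c <-> r5p_c	-1000	1000	PPP
tkt1	x5p_c + r5p_c <-> s7p_c + gap_c	-1000	1000	PPP
tal	s7p_c + gap_c <-> e4p_c + f6p_c	-1000	1000	PPP
tkt2	x5p_c + e4p_c <-> f6p_c + gap_c	-1000	1000	PPP
als	2 pyr_c -> alac_c + co2_c	0	1000	BDO
aldc	alac_c -> actn_c + co2_c	0	1000	BDO
bdh	actn_c + nadh_c <-> bdo_c + nad_c	-1000	1000	BDO
pdc	pyr_c -> acald_c + co2_c	0	0	ethanol
adhA	acald_c + nadh_c <-> etoh_c + nad_c	-1000	1000	ethanol
pdh	pyr_c + coa_c + nad_c -> accoa_c + co2_c + nadh_c	0	1000	TCA
cs	accoa_c + oaa_c + h2o_c -> cit_c + coa_c	0	1000	TCA
acn	cit_c <-> icit_c	-1000	1000	TCA
icd	icit_c + nadp_c <-> akg_c + co2_c + nadph_c	-1000	1000	TCA
ppc	pep_c + co2_c + h2o_c -> oaa_c + pi_c	0	1000	anaplerosis
gpd	dhap_c + nadh_c -> glyc3p_c + nad_c	0	1000	glycerol
gpp	glyc3p_c + h2o_c -> glyc_c + pi_c	0	1000	glycerol
cyo	2 nadh_c + o2_c + adp_c + pi_c -> 2 nad_c + atp_c + 3 h2o_c	0	1000	respiration
nox	2 nadh_c + o2_c -> 2 nad_c + 2 h2o_c	0	1000	respiration
thd	nadph_c + nad_c -> nadp_c + nadh_c	0	1000	redox
ngam	atp_c + h2o_c -> adp_c + pi_c	0	1000	maintenance
biomass	0.205 g6p_c + 0.071 f6p_c + 0.898 r5p_c + 0.361 e4p_c + 0.129 gap_c + 1.496 3pg_c + 0.519 pep_c + 2.833 pyr_c + 3.748 accoa_c + 1.787 oaa_c + 1.079 akg_c + 13.0 nadph_c + 3.0 nad_c + 100.0 atp_c + 100.0 h2o_c -> biomass + 3.748 coa_c + 13.0 nadp_c + 3.0 nadh_c + 100.0 adp_c + 100.0 pi_c	0	1000	biomass
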