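#provenance	curated-skeleton
@metabolite	TYR_c	L-tyrosine	cytosol	0
@metabolite	LDOPA_c	L-DOPA	cytosol	0
@metabolite	DA_c	dopamine	cytosol	0
@metabolite	DA_v	dopamine (vesicular)	vesicle	0
@metabolite	DA_e	dopamine (extracellular)	extracellular	0
@metabolite	OMD_c	3-methoxytyramine	cytosol	0
@metabolite	HVA_c	homovanillic acid	cytosol	0
@metabolite	SAL_c	salsolinol	cytosol	0
@metabolite	ASYN_c	αSYN (monomeric)	cytosol	0
@metabolite	AGG_c	αSYN aggregate (Lewy body)	cytosol	0
@metabolite	ROS_c	reactive oxygen species	cytosol	0
@metabolite	PROT_c	functional protein	cytosol	0
@metabolite	DPROT_c	damaged protein	cytosol	0
@metabolite	UBPROT_c	ubiquitinated damaged protein	cytosol	0
@metabolite	DDNA_c	damaged DNA	cytosol	0
@metabolite	MITO_m	functional mitochondrion	mitochondrion	0
@metabolite	DMITO_m	damaged mitochondrion	mitochondrion	0
@metabolite	CYTC_c	released cytochrome C	cytosol	0
@metabolite	MPTP_e	MPTP	extracellular	0
@metabolite	MPP_c	MPP+	cytosol	0
@metabolite	O2	O2	cytosol	1
@metabolite	H2O	H2O	cytosol	1
@metabolite	NAD	NAD+	cytosol	1
@metabolite	NADH	NADH	cytosol	1
@metabolite	FE2	Fe2+	cytosol	1
@metabolite	FE3	Fe3+	cytosol	1
@metabolite	ATP	ATP	cytosol	1
@metabolite	ADP	ADP+Pi	cytosol	1
id	name	stoichiometry	lower_bound	upper_bound	boundary_kind	speed_tag	best_reference_flux	groups
TYR_IN	tyrosine input	+1 TYR_c	0	100	input	default		
THSynthesis	tyrosine hydroxylase	+1 H2O, +1 LDOPA_c, -1 O2, -1 TYR_c	1.8	2.2	internal	best_et_al	2	
AADCSynthesis	aromatic L-amino acid decarboxylase	+1 DA_c, -1 LDOPA_c	1.8	2.2	internal	best_et_al	2	
OMSynthesis1	COMT O-methylation of DA	-1 DA_c, +1 OMD_c	0	11	internal	best_et_al	10	
OMSynthesis2	COMT O-methylation of L-DOPA	-1 LDOPA_c, +1 OMD_c	0	11	internal	best_et_al	10	
HVASynthesis3	MAO oxidation of 3-methoxytyramine	+1 HVA_c, -1 O2, -1 OMD_c, +1 ROS_c	0	11	internal	best_et_al	10	ROS production (DA)
HVASynthesis4	MAO/COMT route from DA to HVA	-1 DA_c, +1 HVA_c, -1 O2, +1 ROS_c	0	11	internal	best_et_al	10	ROS production (DA)
HVA_OUT	homovanillic acid export	-1 HVA_c	0	100	output	default		
SALSynthesis	salsolinol formation	-1 DA_c, +1 SAL_c	0	30	internal	slow		
SAL_OUT	salsolinol export	-1 SAL_c	0	100	output	default		
VMATTransport	vesicular monoamine transporter	-1 DA_c, +1 DA_v	0.9	1.1	internal	best_et_al	1	
DARelease	vesicular DA release	+1 DA_e, -1 DA_v	0.9	1.1	internal	best_et_al	1	
DATUptake	DAT re-uptake of DA	+1 DA_c, -1 DA_e	0.09000000000000001	0.11000000000000001	internal	best_et_al	0.1	
DA_OUT	extracellular DA clearance	-1 DA_e	0.7200000000000001	0.8800000000000001	output	best_et_al	0.8	Extracellular DA
DAOxidation	DA autoxidation	-1 DA_c, -1 O2, +1 ROS_c	0.9	1.1	internal	best_et_al	1	ROS production (DA)
ASYN_IN	αSYN input	+1 ASYN_c	0	30	input	slow		
DAASYNInteraction	DA-promoted αSYN aggregation	+1 AGG_c, -1 ASYN_c, -1 DA_c	0	100	internal	default		αSYN aggregation
ASYNAggregation	ROS-promoted αSYN aggregation	+1 AGG_c, -1 ASYN_c, -1 ROS_c	0	100	internal	default		αSYN aggregation
DJ1InhibitAggregation	DJ-1 chaperoning of αSYN	-1 ASYN_c, +1 NAD, -1 NADH	0	30	internal	slow		Inhibition of αSYN aggregation by DJ-1
ASYN_OUT	ATP-coupled αSYN export	-1 ASYN_c, -1 ATP	0	100	output	default		αSYN output reaction
AggToxicity	ROS production by αSYN aggregates	-1 AGG_c, -1 O2, +1 ROS_c	0	30	internal	slow		Toxic effect of αSYN aggregates
Apoptosis_LB_OUT	Lewy-body induced apoptosis initiation	-1 AGG_c	0	100	output	default		Apoptosis (LBs)
LysoAggDegradation	lysosomal aggregate degradation	+1 ADP, -1 AGG_c, -1 ATP	0	100	internal	default		Degradation (lysosome)
DJ1ROSElimination	DJ-1 ROS scavenging	+1 H2O, +1 NAD, -1 NADH, -1 ROS_c	0	30	internal	slow		ROS elimination (DJ-1)
ROSDamageProtein	ROS damage to proteins	+1 DPROT_c, -1 PROT_c, -1 ROS_c	0	100	internal	default		ROS damage (protein)
ROSDamageMito	ROS damage to mitochondria	+1 DMITO_m, -1 MITO_m, -1 ROS_c	0	100	internal	default		ROS damage (mitochondria)
ROSDamageDNA	ROS damage to DNA	+1 DDNA_c, -1 ROS_c	0	30	internal	slow		ROS damage (DNA)
DNARepair	DNA repair	+1 ADP, -1 ATP, -1 DDNA_c	0	100	internal	default		
FentonReaction	iron-catalyzed ROS formation	-1 FE2, +1 FE3, -1 O2, +1 ROS_c	0	30	internal	slow		
FeReduction	ferric iron reduction	+1 FE2, -1 FE3, +1 NAD, -1 NADH	0	30	internal	slow		
ProteinSynthesis	protein synthesis	+1 ADP, -1 ATP, +1 PROT_c	0	100	internal	default		
ParkinUbiquitylation	Parkin ubiquitylation of damaged protein	+1 ADP, -1 ATP, -1 DPROT_c, +1 UBPROT_c	0	100	internal	default		
ProteasomeDegradation	proteasomal degradation	+1 ADP, -1 ATP, -1 UBPROT_c	0	30	internal	slow		Degradation (proteasome)
LysoProteinDegradation	lysosomal protein degradation	+1 ADP, -1 ATP, -1 DPROT_c	0	100	internal	default		Degradation (lysosome)
Respiration	respiratory chain ATP production	-1 ADP, +1 ATP, +1 H2O, +1 NAD, -1 NADH, -1 O2	0	100	internal	default		
ComplexIROS	ROS production by complex I	+1 NAD, -1 NADH, -1 O2, +1 ROS_c	0	30	internal	slow		ROS production (mitochondria, complex I)
ComplexIIIROS	ROS production by complex III	+1 NAD, -1 NADH, -1 O2, +1 ROS_c	0	100	internal	default		ROS production (mitochondria, complex III)
MitoBiogenesis	mitochondrial biogenesis	+1 ADP, -1 ATP, +1 MITO_m, -1 PROT_c	0	100	internal	default		Biogenesis of mitochondria
MitoRepair	molecular quality control (PINK1/Parkin/TRAP1)	+1 ADP, -1 ATP, -1 DMITO_m, +1 MITO_m	0	30	internal	slow		
Mitophagy	autophagic removal of damaged mitochondria	+1 ADP, -1 ATP, -1 DMITO_m	0	30	internal	slow		Degradation (mitophagy)
CytCRelease	cytochrome C release by failing mitochondria	+1 CYTC_c, -1 DMITO_m	0	100	internal	default		
Apoptosis_Mito_OUT	mitochondria induced apoptosis initiation	-1 CYTC_c	0	100	output	default		Apoptosis (mitochondria)
MPTP_IN	MPTP exposure	+1 MPTP_e	0	100	input	default		
MPTPUptake	DAT import and MAO-B conversion to MPP+	+1 MPP_c, -1 MPTP_e	0	100	internal	default		
MPPComplexIInhibition	complex I inhibition by MPP+	-1 MPP_c, +1 NAD, -1 NADH, -1 O2, +1 ROS_c	0	30	internal	slow		ROS production (mitochondria, complex I)
MPPMitoDamage	mitochondrial injury by MPP+	+1 DMITO_m, -1 MITO_m, -1 MPP_c	0	100	internal	default		
O2_IN	O2 input	+1 O2	0	100	input	default		
H2O_OUT	H2O output	-1 H2O	0	100	output	default		
NADH_IN	NADH input	+1 NADH	0	100	input	default		
NAD_OUT	NAD+ output	-1 NAD	0	100	output	default		
ATP_IN	ATPase ATP input	+1 ATP	0	100	input	default		
ATP_OUT	ATP surplus export	-1 ATP	0	100	output	default		
ADP_IN	ADP+Pi input	+1 ADP	0	100	input	default		
ADP_OUT	ADP+Pi output	-1 ADP	0	100	output	default		
FE2_IN	Fe2+ input	+1 FE2	0	100	input	default		
FE3_OUT	Fe3+ output	-1 FE3	0	100	output	default		
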