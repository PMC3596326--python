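step_id	ec	pathways	families	substrate	product
atp_phosphohydrolase_1	3.6.1.3	INT	c.37.1.12,c.37.1.20	ATP	ADP
atp_phosphohydrolase_2	3.6.4.1	INT	c.37.1.12,c.37.1.20	ATP	ADP
gmp_synthetase_nh3	6.3.4.1	INT	c.30.1.1,d.142.1.2	XMP	GMP
gmp_synthetase_gln	6.3.5.2	INT	c.23.16.1	XMP	GMP
fgam_synthetase	6.3.5.3	BIO	c.23.16.1	FGAR	FGAM
air_carboxylase	4.1.1.21	BIO	c.30.1.1,d.142.1.2	AIR	CAIR
aicar_formyltransferase_ligase	6.3.4.-	BIO	c.30.1.1,d.142.1.2	AICAR	FAICAR
xanthine_guanine_prtase	2.4.2.8	CAT	c.61.1.1	xanthine	XMP
amp_pyrophosphorylase	2.4.2.7	BIO	c.61.1.1	AICA	AICAR
amidophosphoribosyltransferase	2.4.2.14	BIO	c.61.1.1	PRPP	PRA
adenylosuccinate_lyase_bio	4.3.2.2	BIO	a.127.1.1	SAICAR	AICAR
adenylosuccinate_lyase_int	4.3.2.2	INT	a.127.1.1	adenylosuccinate	AMP
adenylosuccinate_synthase	6.3.4.4	INT	c.37.1.10	IMP	adenylosuccinate
guanylate_kinase	2.7.4.8	INT	c.37.1.1	GMP	GDP
nucleoside_diphosphate_kinase	2.7.4.6	INT	c.37.1.1	GDP	GTP
saicar_synthase	6.3.2.6	BIO	d.143.1.1	CAIR	SAICAR
prpp_synthetase	2.7.6.1	CAR	c.94.1.1	R5P	PRPP
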