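# Published GeneChip result table for the PDAC apoptosis virtual subarray:
# 19 differentially expressed genes (tumor vs microdissected normal ducts),
# linear-scale fold change at printed precision, 23 probesets total.
# has_prior_pdac_reference marks genes with a previously reported role in PDAC.
symbol	name	probesets	fold_change	category	has_prior_pdac_reference
IL1R2	IL1-R2	205403_at	7.1	decoy_receptor	false
BIRC5	Survivin/BIRC5	202094_at,202095_s_at	5.0	apoptosis_inhibitor	true
TNFRSF25	DR3	219423_x_at,210847_x_at	4.1	cell_death_receptor	true
PMAIP1	NOXA	204285_s_at,204286_s_at	3.1	mitochondrial_protein	false
BIRC7	Livin/BIRC7	220451_s_at	2.9	apoptosis_inhibitor	false
MCL1	Mcl-1	241722_x_at	2.8	mitochondrial_protein	true
TRADD	TRADD	1729_at	2.4	signal_molecule	true
IRAK1	Irak, pelle	201587_s_at	2.2	signal_molecule	true
TNFRSF6B	DcR3	206467_x_at	2.1	decoy_receptor	true
BMF	BMF	226530_at	2.1	mitochondrial_protein	false
IRAK3	Irak, pelle	220034_at	2.0	signal_molecule	true
SEPT4	ARTS	210657_s_at	0.49	mitochondrial_protein	false
JUN	AP-1	201466_s_at	0.48	signal_molecule	true
BIRC4	XIAP	225858_s_at	0.48	apoptosis_inhibitor	true
TNFRSF1A	TNF-R1	207643_s_at	0.46	cell_death_receptor	true
BNIP3	BNIP3	201848_s_at,201849_at	0.37	mitochondrial_protein	true
CASP9	Caspase 9	240437_at	0.27	protease	true
TRAF6	TRAF 6	205558_at	0.19	signal_molecule	false
HTRA2	HtrA2/Omi	211152_s_at	0.13	mitochondrial_protein	false
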