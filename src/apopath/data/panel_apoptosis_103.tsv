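# Curated apoptosis gene panel (103 genes).
# The 19 genes of the published GeneChip result table carry their real
# Affymetrix probeset IDs; the remaining 84 apoptosis-pathway genes are the
# package's own curated fill-in with SYNTHETIC probeset IDs (9xxxxx_at range),
# 10 of them unmapped, reproducing the study accounting of 189 probesets for
# 93 mapped genes.
symbol	name	category	probesets
IL1R2	IL1-R2	decoy_receptor	205403_at
BIRC5	Survivin/BIRC5	apoptosis_inhibitor	202094_at,202095_s_at
TNFRSF25	DR3	cell_death_receptor	219423_x_at,210847_x_at
PMAIP1	NOXA	mitochondrial_protein	204285_s_at,204286_s_at
BIRC7	Livin/BIRC7	apoptosis_inhibitor	220451_s_at
MCL1	Mcl-1	mitochondrial_protein	241722_x_at
TRADD	TRADD	signal_molecule	1729_at
IRAK1	Irak, pelle	signal_molecule	201587_s_at
TNFRSF6B	DcR3	decoy_receptor	206467_x_at
BMF	BMF	mitochondrial_protein	226530_at
IRAK3	Irak, pelle	signal_molecule	220034_at
SEPT4	ARTS	mitochondrial_protein	210657_s_at
JUN	AP-1	signal_molecule	201466_s_at
BIRC4	XIAP	apoptosis_inhibitor	225858_s_at
TNFRSF1A	TNF-R1	cell_death_receptor	207643_s_at
BNIP3	BNIP3	mitochondrial_protein	201848_s_at,201849_at
CASP9	Caspase 9	protease	240437_at
TRAF6	TRAF 6	signal_molecule	205558_at
HTRA2	HtrA2/Omi	mitochondrial_protein	211152_s_at
FAS	Fas/CD95	cell_death_receptor	900001_at,900002_at,900003_at
FASLG	Fas ligand	ligand	900004_at,900005_at,900006_at
TNF	TNF-alpha	ligand	900007_at,900008_at,900009_at
TNFSF10	TRAIL	ligand	900010_at,900011_at,900012_at
TNFRSF10A	DR4	cell_death_receptor	900013_at,900014_at,900015_at
TNFRSF10B	DR5	cell_death_receptor	900016_at,900017_at,900018_at
TNFRSF10C	DcR1	decoy_receptor	900019_at,900020_at,900021_at
TNFRSF10D	DcR2	decoy_receptor	900022_at,900023_at,900024_at
TNFRSF1B	TNF-R2	cell_death_receptor	900025_at,900026_at,900027_at
FADD	FADD	signal_molecule	900028_at,900029_at,900030_at
CASP8	Caspase 8	protease	900031_at,900032_at,900033_at
CASP3	Caspase 3	protease	900034_at,900035_at,900036_at
CASP6	Caspase 6	protease	900037_at,900038_at,900039_at
CASP7	Caspase 7	protease	900040_at,900041_at,900042_at
CASP10	Caspase 10	protease	900043_at,900044_at,900045_at
CASP2	Caspase 2	protease	900046_at,900047_at,900048_at
CASP4	Caspase 4	protease	900049_at,900050_at,900051_at
CFLAR	c-FLIP	apoptosis_inhibitor	900052_at,900053_at,900054_at
APAF1	Apaf-1	signal_molecule	900055_at,900056_at
CYCS	Cytochrome c	mitochondrial_protein	900057_at,900058_at
DIABLO	Smac/DIABLO	mitochondrial_protein	900059_at,900060_at
AIFM1	AIF	mitochondrial_protein	900061_at,900062_at
ENDOG	Endonuclease G	mitochondrial_protein	900063_at,900064_at
BCL2	Bcl-2	mitochondrial_protein	900065_at,900066_at
BCL2L1	Bcl-xL	mitochondrial_protein	900067_at,900068_at
BCL2L2	Bcl-w	mitochondrial_protein	900069_at,900070_at
BCL2L11	Bim	mitochondrial_protein	900071_at,900072_at
BAX	Bax	mitochondrial_protein	900073_at,900074_at
BAK1	Bak	mitochondrial_protein	900075_at,900076_at
BID	Bid	mitochondrial_protein	900077_at,900078_at
BAD	Bad	mitochondrial_protein	900079_at,900080_at
BIK	Bik	mitochondrial_protein	900081_at,900082_at
BOK	Bok	mitochondrial_protein	900083_at,900084_at
HRK	Harakiri	mitochondrial_protein	900085_at,900086_at
BBC3	PUMA	mitochondrial_protein	900087_at,900088_at
BNIP3L	NIX	mitochondrial_protein	900089_at,900090_at
BCL2A1	Bfl-1/A1	mitochondrial_protein	900091_at,900092_at
BIRC2	cIAP1	apoptosis_inhibitor	900093_at,900094_at
BIRC3	cIAP2	apoptosis_inhibitor	900095_at,900096_at
BIRC6	Apollon/Bruce	apoptosis_inhibitor	900097_at,900098_at
NAIP	NAIP	apoptosis_inhibitor	900099_at,900100_at
TP53	p53	transcription_factor	900101_at,900102_at
TP73	p73	transcription_factor	900103_at,900104_at
NFKB1	NF-kB p50	transcription_factor	900105_at,900106_at
RELA	NF-kB p65	transcription_factor	900107_at,900108_at
NFKBIA	IkB-alpha	signal_molecule	900109_at,900110_at
CHUK	IKK-alpha	signal_molecule	900111_at,900112_at
IKBKB	IKK-beta	signal_molecule	900113_at,900114_at
MYD88	MyD88	signal_molecule	900115_at,900116_at
IRAK2	IRAK-2	signal_molecule	900117_at,900118_at
IRAK4	IRAK-4	signal_molecule	900119_at,900120_at
TRAF1	TRAF1	signal_molecule	900121_at,900122_at
TRAF2	TRAF2	signal_molecule	900123_at,900124_at
TRAF3	TRAF3	signal_molecule	900125_at,900126_at
RIPK1	RIP1	signal_molecule	900127_at,900128_at
RIPK2	RIP2	signal_molecule	900129_at,900130_at
CRADD	RAIDD	signal_molecule	900131_at,900132_at
DAXX	Daxx	signal_molecule	900133_at,900134_at
MAP3K5	ASK1	signal_molecule	900135_at,900136_at
MAP3K14	NIK	signal_molecule	900137_at,900138_at
MAPK8	JNK1	signal_molecule	900139_at,900140_at
MAPK9	JNK2	signal_molecule	900141_at,900142_at
AKT1	Akt/PKB	signal_molecule	900143_at,900144_at
DFFA	DFF45/ICAD	signal_molecule	900145_at,900146_at
DFFB	DFF40/CAD	signal_molecule	900147_at,900148_at
GZMB	Granzyme B	protease	900149_at,900150_at
PRF1	Perforin	other	900151_at,900152_at
IL1B	IL-1 beta	ligand	900153_at,900154_at
IL1R1	IL1-R1	cell_death_receptor	900155_at,900156_at
MYC	c-Myc	transcription_factor	900157_at,900158_at
E2F1	E2F-1	transcription_factor	900159_at,900160_at
CDKN2A	p16/INK4a	other	900161_at,900162_at
TNFAIP3	A20	signal_molecule	900163_at,900164_at
PEA15	PEA-15	apoptosis_inhibitor	900165_at,900166_at
BCL2L10	Bcl-B	mitochondrial_protein	
BCL2L12	Bcl2-L-12	mitochondrial_protein	
CASP14	Caspase 14	protease	
CARD8	CARDINAL	signal_molecule	
NOL3	ARC	apoptosis_inhibitor	
TNFSF12	TWEAK	ligand	
TNFRSF21	DR6	cell_death_receptor	
AVEN	Aven	apoptosis_inhibitor	
APIP	APIP	other	
MOAP1	MAP-1	mitochondrial_protein	
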