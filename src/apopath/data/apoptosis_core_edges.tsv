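# Curated demonstration edge list for the apoptosis pathway map: canonical
# extrinsic/intrinsic signaling interactions among panel genes, hand-written
# from textbook pathway knowledge (database provenance in the graph).
FASLG	FAS
FASLG	TNFRSF6B
FAS	FADD
FAS	DAXX
FADD	CASP8
FADD	CASP10
CASP8	BID
CASP8	CASP3
CASP8	CFLAR
BID	BAX
BID	BAK1
BAX	CYCS
BAK1	CYCS
CYCS	APAF1
APAF1	CASP9
CASP9	CASP3
CASP3	CASP6
CASP3	CASP7
CASP3	DFFA
DFFA	DFFB
TNF	TNFRSF1A
TNF	TNFRSF1B
TNFRSF1A	TRADD
TNFRSF25	TRADD
TRADD	FADD
TRADD	TRAF2
TRAF2	RIPK1
TRAF2	MAP3K5
RIPK1	IKBKB
CHUK	IKBKB
IKBKB	NFKBIA
NFKBIA	NFKB1
NFKB1	RELA
TNFSF10	TNFRSF10A
TNFSF10	TNFRSF10B
TNFSF10	TNFRSF10C
TNFSF10	TNFRSF10D
TNFRSF10A	FADD
TNFRSF10B	FADD
IL1B	IL1R1
IL1B	IL1R2
IL1R1	MYD88
MYD88	IRAK1
MYD88	IRAK2
MYD88	IRAK4
MYD88	IRAK3
IRAK1	TRAF6
TRAF6	MAP3K14
MAP3K5	MAPK8
MAP3K5	MAPK9
MAPK8	JUN
DAXX	MAP3K5
BIRC4	CASP3
BIRC4	CASP9
BIRC5	DIABLO
BIRC5	CASP9
BIRC7	DIABLO
DIABLO	BIRC4
HTRA2	BIRC4
SEPT4	BIRC4
BCL2	BAX
BCL2	BCL2L11
BCL2	BBC3
BCL2	BNIP3
BCL2	HRK
BCL2	BIK
BCL2L1	BAD
BCL2L1	BMF
MCL1	BCL2L11
MCL1	BAK1
MCL1	PMAIP1
BNIP3L	BCL2
GZMB	CASP3
GZMB	BID
AKT1	BAD
TP53	BAX
TP53	BBC3
E2F1	TP73
MYC	BAX
BCL2A1	BID
BOK	CYCS
AIFM1	ENDOG
PEA15	FADD
TNFAIP3	TRAF2
CRADD	CASP2
CASP2	BID
RIPK2	IKBKB
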