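# TSV: single-target transcription-factor registry, transcribed from the
# printed version-1 / version-2 lists and registry table (synthetic-free
# bookkeeping fixture; discrepant rows are excluded from counts by default).
tf_name	alternative_name	family	org	effector	function	target_operons	version	discrepant	note
BetI		TetR	type_A	Choline	Betaine inhibitor	betIbetBA/betT	1	0
CecR	YbiH	TetR	type_A		Cefoperazone-chloramphenicol sensitivity	cecRybhRGFSR/rhlE	1	0
DecR	YbaO	AsnC	type_B		Regulator of cysteine detoxification	cyuPA	1	0
KdpE		OmpR	type_A	AcP (KdpD)	K+ uptake operon regulator	kdpFABCD/kdpE	1	0
LacI		GalR/LacI	type_A	Allolactose	Lac operon regulator	lacZYA/lacI	1	0
MarR		MarR	type_A	Salicylate	Multiple antibiotic resistance regulator	marC/marRmarAB	1	0
NanR		GntR	type_A	N-Acetylneuraminate	N-Acetylneuraminic acid regulator	nanATEK/nanR	1	0
NimR	YeaM	AraC	type_A		Regulator of 2-nitroimidazole resistance	nimR/nimT	1	0
RpiR		RpiR	type_A	D-Allose	Ribose utilization regulator	rplR/rpiB	1	0
TorR		OmpR	type_A	AcP (TorS)	TMAO reductase regulator	torR/torC	1	0
UlaR		DeoR	type_A		L-Ascorbate utilization regulator	ulaR/ulaG/ulaABCDEF	1	0
UxuR		GntR	type_A	Galacturonate, Glucuronate	Hexuronate regulator	gntP/uxuABuxuR	1	0
XynR	YagI	IclR	type_A		Regulator of xylonate catabolism	yagEF/xynR	1	0	also listed under the spelling XylR
NemR	YdhN	TetR	type_A		Regulator of N-ethyleneimidazole resistance	rplB/rpiRalsBACE	1	1	present only in the printed registry table, not in either in-text list; excluded from counts
CsqR	YihW	DeoR	type_A		Sulfoquinovose catabolism regulator	squUTS/squVcsqR	2	0	spelled CsgR in the printed registry table
CusR		OmpR	type_A	AcP (CusS)	Cu-sensing regulator	cusRcusS/cusCFBA	2	0	conditional: single-target only in the unphosphorylated form
HprR	YedW	OmpR	type_A	AcP (HprS)	Hydrogen peroxide response regulator	hprRhprS/hiuH, cusRS/cusCFBA	2	0
NorR	YgaA	NtrC	type_A		NO reduction detoxification regulator	norR/norVW	2	0
PepA		Trigger	type_B		Peptidase trigger regulator	nfeF/nfeR	2	0
PutA		Trigger	type_A		Proline utilization trigger regulator	putA/putP	2	0
QseA		LysR	type_A	Aromatic carboxylic acid	Quorum-sensing regulator A	aaeXAB/qseA	2	0	conditional: single-target in the pHBA-bound form
RspR	YdfH	GntR	type_B		Mannonate utilization regulator	rspAB	2	0
UvrY		LuxR	type_B		UV response regulator	csrB, yihA/csrC	2	0
ZraR		NtrC	type_A	AcP (ZraS)	Zn resistance-associated regulator	zraP/zraSzraR	2	0
YqhC		AraC	type_A		Glyoxal reductase regulator	yqhC/yqhDdkgA	2	0
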