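position	gene	operon	dna_change	dna_change_ascii	protein_change	annotation
37106	0042	0038 → 0050	A → G	SUB:A>G	K185R	Flagellin
76583	0090	0086 → 0090	A → C	SUB:A>C	Q187H	Putative S-layer function
96733	0119	0119 → 0122	A → G	SUB:A>G	E183G	alpha-subunit proline dehydrogenase
201247	0238	0237 → 0241	A → G	SUB:A>G	E215G	Nitrilase; C-H bond hydrolase
229773	0275	0279 → 0274	C → T	SUB:C>T	R351K	argD; acetyl-lysine amino transferase
327973	0392	0384 → 0393	A → G	SUB:A>G	N.C.	Hypothetical
327976	0392	0384 → 0393	C → A	SUB:C>A	N.C.	Hypothetical
343671	0415	0410 → 0419	G → A	SUB:G>A	G24E	Hypothetical
538367	0634	0631 → 0638	G → A	SUB:G>A	N.C.	Chemotaxis methyl-acceptor
785924	Inter		C → G	SUB:C>G	-
785946	0901	0902 → 0901	ΔΔG	DEL:G	S115fs	F-subunit RNA polymerase (frameshift extends the ORF at C-terminus)
898031	1021	1020 → 1021	ΔΔA	DEL:A	T800fs	Hef nuclease (frameshift extends the ORF at C-terminus)
912171	1039	1039 → 1038	T → C	SUB:T>C	K342R	Cyclic 2'3'-diphosphoglycerate synthetase
914113	1041	1041 → 1042	C → G	SUB:C>G	D132E	Transcription regulator with H-T-H domain
1084046	1236	1236	C → G	SUB:C>G	A209P	AAA+ family ATPase
1124276	1285	1285	C → T	SUB:C>T	G102D	Transcription regulator; LysR/AsnC with HTH domain
1124363	1285	1285	A → C	SUB:A>C	L73R	Transcription regulator; LysR/AsnC with HTH domain
1127248	inter	tRNA	↑T	INS:T	-
1160792	1315	1315	A → C	SUB:A>C	F581V	Phosphoadenosine phosphosulfate reductase
1160804	1315	1315	A → C	SUB:A>C	F577V	Phosphoadenosine phosphosulfate reductase
1252468	1428	1429 → 1429	A → G	SUB:A>G	V20A	Metal-dependent RNase with KH-domain
1361362	1554	1554	↑C	INS:C	P412fs	Cellulose synthetase; glycosyl transferase (frameshift changes C-terminus)
1524161	1729	1729 → 1730	↑A	INS:A	L211fs	Mannosyl transferase (frameshift fuses ORF in-frame with the downstream gene)
1580984	1774	1770 → 1776	ΔΔA	DEL:A	T1069fs	Amylopullanase (frameshift extends the ORF at C-terminus)
1585144	inter		ΔΔG	DEL:G	-
1596662	1789	1789 → 1787	T → C	SUB:T>C	E108G	KaiC domain; recA-like ATPase
1743876	1932	1932 → 1930	↑T	INS:T	N30fs	KaiC domain; ABC-family ATPase (frameshift adds 31 in-frame residues then stop)
1824228	2030	2030	T → C	SUB:T>C	F70L	ACT-domain; amino acid metabolism regulator
1824230	2030	2030	T → A	SUB:T>A	F70L	ACT-domain; amino acid metabolism regulator
1824411	2030	2030	ΔΔG	DEL:G	R131fs	ACT-domain; amino acid metabolism regulator (frameshift changes C-terminus)
1828936	inter		↑G	INS:G	-
1860427	2069	2072 → 2066	↑C	INS:C	V16fs	alpha-subunit of cytosolic NiFe hydrogenase (frameshift truncates at aa 138)
2011218	2222	2222	T → G	SUB:T>G	T242P	ATPase
2050612	2262	2261 → 2263	G → T	SUB:G>T	R119L	PIN domain, likely VAPC toxin
2078803	2298	2298 → 2299	C → G	SUB:C>G	P247A	Anaerobic ribonucleoside reductase class III
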