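accession	gene_name	description	section	log2fc
ZC434.5	ears-1	Glutamyl(E) amino-acyl tRNA synthetase	Translation	-0.51
F31E3.5	eef-1A.1	Eukaryotic translation elongation factor 1-α	Translation	-0.67
F25H5.4	eef-2	Eukaryotic translation elongation factor 2	Translation	-0.53
C27D11.1	egl-45	Eukaryotic translation initiation factor 3 subunit A	Translation	-0.50
F11A3.2	eif-2Bdelta	Eukaryotic translation initiation factor 2B subunit Δ	Translation	-0.79
Y54E2A.11	eif-3.B	Eukaryotic translation initiation factor 3 subunit B	Translation	-0.38
T23D8.4	eif-3.C	Eukaryotic translation initiation factor 3 subunit C	Translation	-0.43
R11A8.6	iars-1	Isoleucyl(I) amino-acyl tRNA synthetase	Translation	-0.26
M110.4	ifg-1	Initiation factor 4G (eIF4G) family	Translation	-0.43
K10C3.5	K10C3.5	Orthologue of Ria1p	Translation	-0.92
R74.1	lars-1	Leucyl(L) amino-acyl tRNA synthetase	Translation	-0.36
C47E12.1	sars-1	Seryl(S) amino-acyl tRNA synthetase	Translation	-0.43
F28H1.3	aars-2	Alanyl(A) amino-acyl tRNA synthetase	Translation	-0.46
K08F11.3	cif-1	COP9/signalosome and eIF3 complex shared subunit	Translation	-0.37
Y41E3.10	eef-1B.2	Eukaryotic translation elongation factor	Translation	-0.31
Y37E3.10	eif-2A	Eukaryotic initiation factor	Translation	-1.06
R08D7.3	eif-3.D	Eukaryotic initiation factor	Translation	-1.61
Y40B1B.5	eif-3.J	Eukaryotic initiation factor	Translation	-1.24
C17G10.9	eif-3.L	Eukaryotic initiation factor	Translation	-0.61
C47B2.5	eif-6	Eukaryotic initiation factor	Translation	-0.53
T05H4.6	erfa-1	Eukaryotic release factor homolog	Translation	-0.30
F22B5.9	fars-3	Phenylalanyl(F) amino-acyl tRNA synthetase	Translation	-1.65
T10F2.1	gars-1	Glycyl(G) amino-acyl tRNA synthetase	Translation	-0.41
F53A2.6	ife-1	Initiation factor 4E (eIF4E) family	Translation	-0.72
B0348.6	ife-3	Initiation factor 4E (eIF4E) family	Translation	-0.55
T05G5.10	iff-1	Initiation factor five (eIF-5A) homolog	Translation	-0.31
Y54F10BM.2	iffb-1	Initiation factor five B (eIF5B)	Translation	-0.75
F57B9.6	inf-1	Initiation factor	Translation	-0.31
T02G5.9	kars-1	Lysyl(K) amino-acyl tRNA synthetase	Translation	-0.30
F58B3.5	mars-1	Methionyl(M) amino-acyl tRNA synthetase	Translation	-0.62
F22D6.3	nars-1	Asparaginyl(N) amino-acyl tRNA synthetase	Translation	-0.64
Y41E3.4	qars-1	Glutaminyl(Q) amino-acyl tRNA synthetase	Translation	-0.43
F26F4.10	rars-1	Arginyl(R) amino-acyl tRNA synthetase	Translation	-0.55
C47D12.6	tars-1	Threonyl(T) amino-acyl tRNA synthetase	Translation	-0.44
Y87G2A.5	vrs-2	Valyl(V) amino-acyl tRNA synthetase	Translation	-0.41
Y80D3A.1	wars-1	Tryptophanyl(W) amino-acyl tRNA synthetase	Translation	-0.67
Y105E8A.19	yars-1	Tyrosinyl(Y) amino-acyl tRNA synthetase	Translation	-0.90
Y71F9AL.13	rpl-1	Large ribosomal subunit L1 protein	Ribosome	-0.53
B0250.1	rpl-2	Large ribosomal subunit L2 protein	Ribosome	-0.82
F13B10.2	rpl-3	Large ribosomal subunit L3 protein	Ribosome	-0.75
B0041.4	rpl-4	Large ribosomal subunit L4 protein	Ribosome	-0.95
54C9.5	rpl-5	Large ribosomal subunit L5 protein	Ribosome	-0.58
R151.3	rpl-6	Large ribosomal subunit L6 protein	Ribosome	-0.37
Y24D9A.4	rpl-7A	Large ribosomal subunit L7A protein	Ribosome	-0.44
R13A5.8	rpl-9	Large ribosomal subunit L9 protein	Ribosome	-0.67
JC8.3	rpl-12	Large ribosomal subunit L12 protein	Ribosome	-0.48
C32E8.2	rpl-13	Large ribosomal subunit L13 protein	Ribosome	-0.56
C04F12.4	rpl-14	Large ribosomal subunit L14 protein	Ribosome	-0.30
K11H12.2	rpl-15	Large ribosomal subunit L15 protein	Ribosome	-0.61
M01F1.2	rpl-16	Large ribosomal subunit L16 protein	Ribosome	-0.73
Y48G8AL.8	rpl-17	Large ribosomal subunit L17 protein	Ribosome	-0.45
Y45F10D.12	rpl-18	Large ribosomal subunit L18 protein	Ribosome	-0.66
C09D4.5	rpl-19	Large ribosomal subunit L18A protein	Ribosome	-0.51
E04A4.8	rpl-20	Large ribosomal subunit L20 protein	Ribosome	-0.69
C14B9.7	rpl-21	Large ribosomal subunit L18A protein	Ribosome	-0.51
D1007.12	rpl-24.1	Large ribosomal subunit L20 protein	Ribosome	-0.51
F28C6.7	rpl-26	Large ribosomal subunit L18A protein	Ribosome	-0.29
T24B8.1	rpl-32	Large ribosomal subunit L20 protein	Ribosome	-0.26
F37C12.4	rpl-36	Large ribosomal subunit L18A protein	Ribosome	-0.39
C26F1.9	rpl-39	Large ribosomal subunit L20 protein	Ribosome	-0.98
C09H10.2	rpl-41	Large ribosomal subunit L18A protein	Ribosome	-0.41
Y48B6A.2	rpl-43	Large ribosomal subunit L20 protein	Ribosome	-0.50
B0393.1	rps-0	Small ribosomal subunit S protein	Ribosome	-0.49
F56F3.5	rps-1	Small ribosomal subunit S1 protein	Ribosome	-0.57
C49H3.11	rps-2	Small ribosomal subunit S2 protein	Ribosome	-0.50
C23G10.3	rps-3	Small ribosomal subunit S3 protein	Ribosome	-0.50
Y43B11AR.4	rps-4	Small ribosomal subunit S4 protein	Ribosome	-0.54
T05E11.1	rps-5	Small ribosomal subunit S5 protein	Ribosome	-0.45
Y71A12B.1	rps-6	Small ribosomal subunit S6 protein	Ribosome	-0.83
ZC434.2	rps-7	Small ribosomal subunit S7 protein	Ribosome	-0.39
F40F11.1	rps-11	Small ribosomal subunit S11 protein	Ribosome	-0.57
F37C12.9	rps-14	Small ribosomal subunit S14 protein	Ribosome	-0.51
T08B2.10	rps-17	Small ribosomal subunit S17 protein	Ribosome	-0.41
Y57G11C.16	rps-18	Small ribosomal subunit S18 protein	Ribosome	-0.48
F37C12.11	rps-21	Small ribosomal subunit S21 protein	Ribosome	-0.35
F53A3.3	rps-22	Small ribosomal subunit S22 protein	Ribosome	-0.44
T07A9.11	rps-24	Small ribosomal subunit S24 protein	Ribosome	-0.53
H06I04.4	ubl-1	Small ribosomal subunit S27a protein	Ribosome	-0.37
Y62E10A.1	rla-2	Ribosomal protein, large subunit, acidic (P1)	Ribosome	-0.39
F10B5.1	rpl-10	Large ribosomal subunit L10 protein	Ribosome	-0.42
T22F3.4	rpl-11.1	Large ribosomal subunit L11 protein	Ribosome	-1.26
C27A2.2	rpl-22	Large ribosomal subunit L22 protein	Ribosome	-0.47
C03D6.8	rpl-24.2	Large ribosomal subunit L24 protein	Ribosome	-0.68
F52B5.6	rpl-25.2	Large ribosomal subunit L23a protein	Ribosome	-0.82
C53H9.1	rpl-27	Large ribosomal subunit L27 protein	Ribosome	-0.52
R11D1.8	rpl-28	Large ribosomal subunit L28 protein	Ribosome	-0.65
C42C1.14	rpl-34	Large ribosomal subunit L34 protein	Ribosome	-0.53
ZK1010.1	rpl-40	Large ribosomal subunit L40 protein	Ribosome	-0.52
C16A3.9	rps-13	Small ribosomal subunit S13 protein	Ribosome	-0.57
F36A2.6	rps-15	Small ribosomal subunit S15 protein	Ribosome	-0.49
T05F1.3	rps-19	Small ribosomal subunit S19 protein	Ribosome	-0.44
Y105E8A.16	rps-20	Small ribosomal subunit S20 protein	Ribosome	-0.47
F28D1.7	rps-23	Small ribosomal subunit S23 protein	Ribosome	-0.62
Y41D4B.5	rps-28	Small ribosomal subunit S28 protein	Ribosome	-0.64
C26F1.4	rps-30	Small ribosomal subunit S30 protein and ubiquitin	Ribosome	-0.43
F42C5.8	rps-8	Small ribosomal subunit S8 protein	Ribosome	-0.70
F40F8.10	rps-9	Small ribosomal subunit S9 protein	Ribosome	-0.41
W01D2.1	W01D2.1	Orthologue of human RPL37 (ribosomal protein L37)	Ribosome	-0.41
Y37E3.8	Y37E3.8	Orthologue of human RPL27A (ribosomal protein L27a)	Ribosome	-0.40
W03H9.4	cacn-1	CACtiN (Drosophila cactus interacting protein) homolog	mRNA processing	-0.65
F32B6.3	F32B6.3	Pre-mRNA processing factor 18	mRNA processing	-0.85
K07C5.6	K07C5.6	Homologue of splicing factor SLU7	mRNA processing	-0.95
F33A8.1	let-858	Similarity to eukaryotic initiation factor eIF-4 γ	mRNA processing	-0.47
C04H5.6	mog-4	DEAH helicase	mRNA processing	-0.65
EEED8.5	mog-5	DEAH box helicase 8	mRNA processing	-0.52
C50C3.6	prp-8	Yeast PRP (splicing factor) related	mRNA processing	-0.27
Y46G5A.4	snrp-200	Small nuclear ribonucleoprotein homologue	mRNA processing	-0.38
C07E3.1	stip-1	Septin- and tuftelin-interacting protein homologue	mRNA processing	-0.84
W04D2.6	W04D2.6	Orthologue of human RBM25	mRNA processing	-0.57
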