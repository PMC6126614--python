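accession	gene_name	description	section	log2fc
C16A3.5	C16A3.5	Orthologue B9 subunit of the mitochondrial complex I	Complex I	0.42
C18E9.4	C18E9.4	Orthologue B12 subunit of the mitochondrial complex I	Complex I	0.61
C25H3.9	C25H3.9	Orthologue B5 subunit of the mitochondrial complex I	Complex I	0.40
C33A12.1	C33A12.1	Orthologue A5/B13 subunit of the mitochondrial complex I	Complex I	0.43
C34B2.8	C34B2.8	Orthologue A13 subunit of the mitochondrial complex I	Complex I	0.48
F37C12.3	F37C12.3	Orthologue AB1 subunit of the mitochondrial complex I	Complex I	0.53
F42G8.10	F42G8.10	Orthologue B11 subunit of the mitochondrial complex I	Complex I	0.38
F44G4.2	F44G4.2	Orthologue B2 subunit of the mitochondrial complex I	Complex I	0.54
F53F4.10	F53F4.10	Orthologue NADH-UQ oxidoreductase flavoprotein 2	Complex I	0.45
ZK973.10	lpd-5	NADH-UQ oxidoreductase fe-s protein 4	Complex I	0.37
W10D5.2	nduf-7	NADH-UQ oxidoreductase fe-s protein 7	Complex I	0.47
C09H10.3	nuo-1	NADH UQ oxidoreductase 1	Complex I	0.35
T10E9.7	nuo-2	NADH UQ oxidoreductase 2	Complex I	0.47
W01A8.4	nuo-6	NADH UQ oxidoreductase 6	Complex I	0.47
T20H4.5	T20H4.5	Orthologue NADH-UQ oxidoreductase Fe-S protein 8	Complex I	0.39
Y53G8AL.2	Y53G8AL.2	Orthologue A9 subunit of the mitochondrial complex I	Complex I	0.48
F42A8.2	sdhb-1	Succinate dehydrogenase complex subunit B	Complex II	0.37
F33A8.5	sdhd-1	Succinate dehydrogenase complex subunit D	Complex II	0.74
C54G4.8	cyc-1	Cytochrome C reductase	Complex III	0.35
F42G8.12	isp-1	Rieske iron sulphur protein subunit of the mitochondrial complex III	Complex III	0.27
R07E4.3	R07E4.3	Orthologue subunit VII ubiquinol-cytochrome c reductase complex III	Complex III	0.54
T02H6.11	T02H6.11	Ubiquinol-cytochrome c reductase binding protein	Complex III	0.40
T27E9.2	T27E9.2	Ubiquinol-cytochrome c reductase hinge protein	Complex III	0.54
F57B10.14	ucr-11	Ubiquinol-cytochrome c oxidoreductase complex	Complex III	0.75
F26E4.9	cco-1	Cytochrome C oxidase	Complex IV	0.46
Y37D8A.14	cco-2	Cytochrome C oxidase	Complex IV	0.46
F26E4.6	F26E4.6	Orthologue cytochrome c oxidase subunit 7C	Complex IV	0.55
F29C4.2	F29C4.2	Orthologue cytochrome c oxidase subunit 6C	Complex IV	0.66
F54D8.2	tag-174	Orthologue cytochrome c oxidase subunit 6A2	Complex IV	0.45
Y71H2AM.5	Y71H2AM.5	Orthologue cytochrome c oxidase subunit 6B1	Complex IV	0.48
C53B7.4	asg-2	ATP synthase G homolog	Complex V	0.79
C06H2.1	atp-5	ATP synthase subunit	Complex V	0.45
F32D1.2	hpo-18	Orthologue of ATP synthase, H+ transporting, mitochondrial F1 complex, ε subunit	Complex V	0.56
R04F11.2	R04F11.2	Orthologue of ATP synthase, H+ transporting, mitochondrial Fo complex, ε subunit	Complex V	0.51
R53.4	R53.4	Mitochondrial ATP synthase subunit f homolog	Complex V	0.34
R10E11.8	vha-1	Vacuolar H ATPase 1	Complex V	0.50
R10E11.2	vha-2	Vacuolar H ATPase 2	Complex V	0.63
Y38F2AL.4	vha-3	Vacuolar H ATPase 3	Complex V	0.58
T01H3.1	vha-4	Vacuolar H ATPase 4	Complex V	0.61
VW02B12L.1	vha-6	Vacuolar H ATPase 6	Complex V	0.59
C17H12.14	vha-8	Vacuolar H ATPase 8	Complex V	0.66
ZK970.4	vha-9	Vacuolar H ATPase 9	Complex V	0.43
F46F11.5	vha-10	Vacuolar H ATPase 10	Complex V	0.64
Y38F2AL.3	vha-11	Vacuolar H ATPase 11	Complex V	0.58
F20B6.2	vha-12	Vacuolar H ATPase 12	Complex V	0.34
Y49A3A.2	vha-13	Vacuolar H ATPase 13	Complex V	0.35
F55H2.2	vha-14	Vacuolar H ATPase 14	Complex V	0.49
T14F9.1	vha-15	Vacuolar H ATPase 15	Complex V	0.51
C30F8.2	vha-16	Vacuolar H ATPase 16	Complex V	0.55
Y69A2AR.18	Y69A2AR.18	Orthologue of ATP synthase, H+ transporting, mitochondrial F1 complex, γ subunit	Complex V	0.25
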