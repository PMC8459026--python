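# Copy-number registry of fatty-acid biosynthesis enzymes (homologs of 30
# Arabidopsis thaliana query genes) in cacao and shea.
enzyme	family	description	A_thaliana	T_cacao	V_paradoxa
BCCP	ACCase	Homomeric Acetyl-CoA Carboxylase BCCP subunit	2	3	3
CAC2	ACCase	Homomeric Acetyl-CoA Carboxylase BC subunit	1	1	1
CAC3	ACCase	Homomeric Acetyl-CoA Carboxylase alpha-CT subunit	1	2	2
KASI	KAS	Ketoacyl-ACP synthase I	1	2	4
KASII	KAS	Ketoacyl-ACP synthase II	1	3	3
KASIII	KAS	Ketoacyl-ACP synthase III	1	1	2
FATA	FAT	Acyl-ACP Thioesterase Fat A	2	1	2
FATB	FAT	Acyl-ACP Thioesterase Fat B	1	1	2
FAD2	FAD2	ER Oleate Desaturase	1	2	4
FAD3	FAD3	ER Linoleate Desaturase	1	3	5
FAX1	FAX	Fatty acid exporter 1	1	1	1
FAX2	FAX	Fatty acid exporter 2	1	1	2
FAX4	FAX	Fatty acid exporter 4	1	1	0
LACS	LACS	Long Chain Acyl-CoA Synthetase	9	7	8
ACBP	ACBP	Acyl-CoA-binding protein	6	6	6
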