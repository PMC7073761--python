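gene_id	symbol	group	chromosome	band	gene_size_bp	exon_count	lir	actin_retrogene
ENSG00000188877	POTEA	I	8	8p11.1	71036	14	half	no
ENSG00000233917	POTEB	II	15	15q11.2	31375	11	half	no
ENSG00000230031	POTEB2	II	15	15q11.2	30943	11	half	no
ENSG00000278522	POTEB3	II	15	15q11.2	32209	11	half	no
ENSG00000183206	POTEC	II	18	18p11.21	36247	11	half	no
ENSG00000166351	POTED	II	21	21q11.2	31728	11	half	no
ENSG00000188219	POTEE	III	2	2q21.1	47212	15	full	yes
ENSG00000196604	POTEF	III	2	2q21.1	55688	17	full	yes
ENSG00000196834	POTEI	III	2	2q21.1	50253	15	full	yes
ENSG00000222038	POTEJ	III	2	2q21.1	46611	15	full	yes
ENSG00000204434	POTEKP	ambiguous	2	2q21.1	36396	11	full	out_of_cds
ENSG00000187537	POTEG	IV	14	14q11.2	31856	12	full	out_of_cds
ENSG00000198062	POTEH	IV	22	22q11.1	31606	12	full	out_of_cds
ENSG00000222036	POTEM	IV	14	14q11.2	36319	12	full	out_of_cds
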