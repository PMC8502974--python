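gene	genomic_change	zygosity	inheritance	panel	cadd	population_freq	genotype_P1	genotype_P2
UNC80	chr2:g.210678477C>T	homozygous	AR	ID			T/T	C/T
POLA2	chr11:g.65063046T>C	homozygous	NA	Autism candidate			C/C	T/C
KCNK7	chr11:g.65363204C>T	homozygous	NA	Autism candidate			T/T	C/T
CEP290	chr12:g.88500631C>A	homozygous	AR	ID			A/A	C/A
ACE	chr17:g.61566077G>C	homozygous	NA	Autism candidate			C/C	G/G
ARFGEF2	chr20:g.47632862A>G	homozygous	AR	ID			G/G	A/G
PLA2G6	chr22:g.38508527C>T	homozygous	AR	ID			T/T	C/C
BCOR	chrX:g.39932734G>C	homozygous	XLD	ID			C	G
BRWD3	chrX:g.79938123T>C	homozygous	XLR	ID			T	C
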