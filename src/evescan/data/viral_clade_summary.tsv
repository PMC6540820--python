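genome_structure	clade	protein	n_eves	n_exogenous_proteins
ssRNA	Bunya-Arena	Nucleoprotein	18	18
ssRNA	Bunya-Arena	RdRP	3	12
ssRNA	Hepe-Virga	RdRP	3	15
ssRNA	Mono-Chu	Glycoprotein	227	17
ssRNA	Mono-Chu	Nucleoprotein	2	12
ssRNA	Mono-Chu	RdRP	24	30
ssRNA	Narna-Levi	RdRP	2	15
ssRNA	Partiti-Picobirna	Capsid	5	7
ssRNA	Partiti-Picobirna	RdRP	4	16
ssRNA	Qinvirus	RdRP	3	10
ssRNA	Toti-Chryso	Coat	12	12
ssRNA	Toti-Chryso	RdRP	1	15
ssDNA	Circoviridae	rep-associated protein	2	10
ssDNA	Parvoviridae	VP1	3	10
ssDNA	Parvoviridae	Non-structural protein 1	8	18
ssDNA	Parvoviridae	Non-structural protein 2	1	12
dsDNA	Baculoviridae	Bro-a	1	12
dsDNA	Baculoviridae	PIF-1	8	18
dsDNA	Baculoviridae	PIF-2	7	14
dsDNA	Baculoviridae	PIF-3	1	12
dsDNA	Poxviridae	Tryptophan	2	6
dsDNA	Poxviridae	RNA-polymerase RP0147	1	7
dsDNA	Polydnaviridae	Pox A32	3	6
ssRNA(RT)	Metaviridae	ORF B	93	NA
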