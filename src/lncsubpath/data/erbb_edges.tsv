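pathway_id	gene_a	gene_b
erbb	EGF	EGFR
erbb	TGFA	EGFR
erbb	AREG	EGFR
erbb	BTC	EGFR
erbb	BTC	ERBB4
erbb	HBEGF	EGFR
erbb	HBEGF	ERBB4
erbb	EREG	EGFR
erbb	EREG	ERBB4
erbb	NRG1	ERBB3
erbb	NRG1	ERBB4
erbb	NRG2	ERBB3
erbb	NRG2	ERBB4
erbb	EGFR	ERBB2
erbb	ERBB2	ERBB3
erbb	ERBB2	ERBB4
erbb	EGFR	GRB2
erbb	ERBB2	GRB2
erbb	EGFR	SHC1
erbb	ERBB2	SHC1
erbb	ERBB3	SHC1
erbb	ERBB4	SHC1
erbb	SHC1	GRB2
erbb	GRB2	SOS1
erbb	GRB2	GAB1
erbb	EGFR	PLCG1
erbb	PLCG1	PRKCA
erbb	EGFR	SRC
erbb	SRC	STAT5A
erbb	EGFR	CBL
erbb	EGFR	NCK1
erbb	NCK1	PAK1
erbb	PAK1	MAP2K4
erbb	MAP2K4	MAPK8
erbb	MAPK8	JUN
erbb	SOS1	HRAS
erbb	SOS1	KRAS
erbb	HRAS	RAF1
erbb	KRAS	RAF1
erbb	HRAS	BRAF
erbb	KRAS	BRAF
erbb	RAF1	MAP2K1
erbb	RAF1	MAP2K2
erbb	BRAF	MAP2K1
erbb	BRAF	MAP2K2
erbb	MAP2K1	MAPK1
erbb	MAP2K1	MAPK3
erbb	MAP2K2	MAPK1
erbb	MAP2K2	MAPK3
erbb	MAPK1	ELK1
erbb	MAPK3	ELK1
erbb	MAPK1	MYC
erbb	MAPK3	MYC
erbb	GAB1	PIK3CA
erbb	ERBB3	PIK3CA
erbb	ERBB3	PIK3R1
erbb	PIK3CA	PIK3R1
erbb	PIK3CA	AKT1
erbb	PIK3R1	AKT1
erbb	AKT1	MTOR
erbb	MTOR	RPS6KB1
erbb	MTOR	EIF4EBP1
erbb	AKT1	BAD
erbb	AKT1	GSK3B
erbb	AKT1	CDKN1A
erbb	AKT1	CDKN1B
erbb	PRKCA	RAF1
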