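Complex	Drug	Target	ProteinRMSDMean	ProteinRMSDSD	HBondMean	HBondSD	ProteinSASA	LigandSASA	logBB
Vorapaxar-APP	Vorapaxar	APP	4.15		15.20				-0.15
Bictegravir-ETV6	Bictegravir	ETV6	3.34						-1.105
Olaparib-ETV6	Olaparib	ETV6	3.25		71.20				-0.78
Tolnaftate-ETV6	Tolnaftate	ETV6	3.13		65.94		82.89	5.70	0.71
Fluspirilene-ETV6	Fluspirilene	ETV6	3.26		68.39		87.00	7.79	0.42
Lasmiditan-ETV6	Lasmiditan	ETV6	2.98	0.69	68.38	5.22	87.00	8.68	-0.29
Lisuride-ETV6	Lisuride	ETV6	4.17		65.57		85.03	6.01	-0.19
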