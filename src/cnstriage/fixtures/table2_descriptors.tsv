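Drug	LogP	TPSA	MW	pKa	LogD	PgpEfflux	BBBPermeability	logBB	logBBInterpretation	DERTargetsAbove7	StudiedInAD
Tolnaftate	4.95	12.47	307.42	8.4	3.91	1	1	0.71	Very high	18	no
Methotrexate	0.27	210.54	454.45	5.5	0.26	0	0	-2.94	Very low	18	yes
Lisuride	2.84	51.37	338.46	7.8	2.30	0	1	-0.19	Moderate	13	yes
Vardenafil	2.07	112.9	488.61	6.4	2.03	0	0	-1.22	Very low	16	yes
Fluspirilene	5.31	35.58	475.58	8.2	4.44	1	1	0.42	High	18	yes
Sofosbuvir	1.66	158.18	529.46	9.1	-0.05	0	0	-1.95	Very low	18	yes
Vorapaxar	5.63	77.52	492.59	5.9	5.62	0	1	-0.15	Moderate	15	no
Olaparib	2.35	86.37	434.47	7.2	2.13	0	1	-0.78	Very low	11	yes
Alatrofloxacin	0.90	159.65	558.52	6.1	0.88	0	0	-2.09	Very low	15	no
Lasmiditan	3.28	62.3	377.37	8	2.58	0	1	-0.29	Moderate	13	no
Bictegravir	1.63	100.87	449.39	6.8	1.54	0	0	-1.11	Very low	17	no
Atogepant	3.95	104.29	603.52	7.5	3.59	0	0	-0.80	Very low	14	no
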