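Drug	APP	PAX6	ZEB2	ETV6	ST18
Vorapaxar	-8.489	-7.715	-7.945	-7.51	-8.448
Fluspirilene	-8.251	-8.616	-7.899	-7.012	-7.611
Alatrofloxacin	-8.066	-7.291	-7.906	-7.095	-8.181
Atogepant	-7.962	-8.107	-7.563	-7.42	-7.823
Tolnaftate	-7.747	-7.913	-8.04	-7.698	-7.631
Bictegravir	-7.699	-7.795	-7.802	-7.125	-8.198
Vardenafil	-7.62	-6.914	-7.345	-7.321	-8.278
Lisuride	-7.234	-8.259	-7.409	-7.591	-7.677
Lasmiditan	-7.19	-7.181	-7.76	-7.561	-7.751
Olaparib	-7.118	-7.545	-7.42	-6.721	-7.656
Sofosbuvir	-7.027	-7.393	-7.761	-7.197	-7.902
Methotrexate	-6.788	-7.065	-6.762	-6.342	-7.165
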