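narrative_symbol	table_symbols	category
SDHA	SDHA	mitochondrial_metabolism
CS	CS	mitochondrial_metabolism
PARK7	PARK7	oxidative_stress_response
PSMA5	PSMA8	proteasomal_degradation
PSMB	PSMB3|PSMB5|PSMB10	proteasomal_degradation
PSMC3	PSMC1B	proteasomal_degradation
PSMC5	PSMC5	proteasomal_degradation
PSMD11	PSMD11B	proteasomal_degradation
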