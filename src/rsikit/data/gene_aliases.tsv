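alias	canonical
c-JUN	JUN
PKC	PRKCB
Rel A	RELA
cABL	ABL1
CD8	CD8A
PD1	PDCD1
PDL1	CD274
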