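subject_id	label	hpo_terms
REF_MELAS	MELAS-like (m.3243A>G)	FX:0000011;FX:0000016;FX:0000017;FX:0000027;FX:0000061;FX:0000091
REF_MERRF	MERRF-like (m.8344A>G)	FX:0000012;FX:0000015;FX:0000018;FX:0000042;FX:0000052
REF_NARP	NARP-like (m.8993T>G)	FX:0000018;FX:0000020;FX:0000021;FX:0000037
REF_SNHL	SNHL-like (m.1555A>G)	FX:0000042;FX:0000043
REF_LHON	LHON-like (m.11778G>A)	FX:0000034;FX:0000035
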