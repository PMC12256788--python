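subject_id	hpo_terms
S1	FX:0000011;FX:0000017;FX:0000027;FX:0000061
S2	FX:0000012;FX:0000015;FX:0000018;FX:0000042
S3	FX:0000026
S4	FX:0000018;FX:0000020;FX:0000037
S5	FX:0000056
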