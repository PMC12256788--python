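sample_id	assembled_fraction	mean_depth	assay	tissue
S1	0.95	45	ES	blood
S2	0.8	30	ES	blood
S3	0.4	20	ES	blood
S4	0.9	60	GS	blood
S5	0.85	3	ES	blood
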