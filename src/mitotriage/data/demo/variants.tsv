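sample_id	position	ref	alt	heteroplasmy	depth
S1	7028	C	T	0.99	50
S1	2706	A	G	1.0	48
S1	3243	A	G	0.35	52
S1	750	A	G	1.0	45
S1	16189	T	C	0.9	40
S1	4308	G	A	0.008	44
S2	295	C	T	1.0	31
S2	489	T	C	0.98	29
S2	8344	A	G	0.22	33
S2	11778	G	A	0.005	30
S2	1555	A	G	1.0	28
S3	3243	A	G	0.5	21
S3	8993	T	G	0.8	19
S4	1438	A	G	1.0	61
S4	8993	T	G	0.45	58
S4	12612	A	G	0.95	60
S4	5656	A	G	0.7	55
S4	9032	T	C	0.02	57
S5	3460	G	A	1.0	4
S5	14484	T	C	0.9	3
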