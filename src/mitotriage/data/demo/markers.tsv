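haplogroup	position	ref	alt
H	1438	A	G
H	2706	A	G
H	7028	C	T
J	295	C	T
J	489	T	C
J	10398	A	G
J	12612	A	G
J	13708	G	A
K	1189	T	C
K	9055	G	A
K	11299	T	C
T	709	G	A
T	1888	G	A
T	4917	A	G
U	11467	A	G
U	12308	A	G
U	12372	G	A
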