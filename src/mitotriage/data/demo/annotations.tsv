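position	ref	alt	mitomap_status	mitomap_af	in_mitophen	gene	reportable
3243	A	G	confirmed		true	MT-TL1	false
8344	A	G	confirmed		true	MT-TK	false
8993	T	G	reported	0.0005	false	MT-ATP6	false
11778	G	A	confirmed		true	MT-ND4	true
1555	A	G	reported	0.001	true	MT-RNR1	true
3460	G	A	confirmed		true	MT-ND1	true
14484	T	C	confirmed		true	MT-ND6	true
4308	G	A	reported	0.001	true	MT-TQ	false
5656	A	G	reported	0.01	false	MT-NC2	false
9032	T	C	reported		false	MT-ATP6	false
750	A	G	reported	0.05	false	MT-RNR1	false
16189	T	C	reported	0.02	false	MT-DLOOP	false
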