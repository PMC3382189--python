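id	smiles	activity_class	amine_config_policy
(R)-NPA	CCCN1CCC2=CC(O)=C(O)C3=C2[C@H]1CC1=CC=CC=C13	full	enumerate
talipexole	C=CCN1CCc2nc(N)sc2CC1	full	enumerate
(R)-sumanirole	CN[C@@H]1Cc2cccc3c2N(C1)C(=O)N3	full	fixed
(R,R)-PHNO	CCCN1CCO[C@@H]2c3cc(O)ccc3CC[C@@H]12	full	fixed
nPr-DHX	OC1=C(O)C=C2CC[C@H]3N(CCC)Cc4ccccc4[C@@H]3C2=C1	full	enumerate
(3S,9R)-6a	CCCN1CC[C@H]2c3ccc(O)cc3CC[C@@H]2C1	full	enumerate
quinpirole	CCCN1CC[C@H]2Cc3c[nH]nc3C[C@@H]2C1	full	enumerate
(S)-5-OH-DPAT	CCCN(CCC)[C@H]1CCc2c(O)cccc2C1	full	fixed
(S)-DPAT	CCCN(CCC)[C@H]1CCc2ccccc2C1	full	fixed
(R)-3-PPP	CCCN1CCC[C@H](c2cccc(O)c2)C1	full	enumerate
apomorphine	CN1CCC2=CC(O)=C(O)C3=C2[C@H]1CC1=CC=CC=C13	full	enumerate
dopamine	NCCc1ccc(O)c(O)c1	full	fixed
A70108	NC[C@@H]1O[C@@H](c2ccccc2)Cc2c(O)c(O)ccc21	full	fixed
(R)-5-OH-DPAT	CCCN(CCC)[C@@H]1CCc2c(O)cccc2C1	partial	fixed
(S)-3-PPP	CCCN1CCC[C@@H](c2cccc(O)c2)C1	partial	enumerate
(S)-6-OH-DPAT	CCCN(CCC)[C@H]1CCc2cc(O)ccc2C1	partial	fixed
(R)-7-OH-DPAT	CCCN(CCC)[C@@H]1CCc2ccc(O)cc2C1	partial	fixed
DHX	OC1=C(O)C=C2CC[C@H]3NCc4ccccc4[C@@H]3C2=C1	partial	fixed
(S)-sumanirole	CN[C@H]1Cc2cccc3c2N(C1)C(=O)N3	inactive	fixed
(S,S)-PHNO	CCCN1CCO[C@H]2c3cc(O)ccc3CC[C@H]12	inactive	enumerate
(3R,9S)-6b	CCCN1CC[C@@H]2c3ccc(O)cc3CC[C@H]2C1	inactive	enumerate
(S)-7-OH-DPAT	CCCN(CCC)[C@H]1CCc2ccc(O)cc2C1	inactive	fixed
doxanthrine	OC1=C(O)C=C2OC[C@H]3NCc4ccccc4[C@@H]3C2=C1	inactive	fixed
A86929	CCCc1cc2c(s1)CN[C@H]1CCC3=CC(O)=C(O)C=C3[C@H]21	inactive	fixed
A77636	NC[C@@H]1O[C@@H](C23CC4CC(CC(C4)C2)C3)Cc2c(O)c(O)ccc21	inactive	fixed
A77641	NC[C@H]1O[C@H](C23CC4CC(CC(C4)C2)C3)Cc2c(O)c(O)ccc21	inactive	fixed
A70360	NC[C@H]1O[C@H](c2ccccc2)Cc2c(O)c(O)ccc21	inactive	fixed
SKF38393	OC1=C(O)C=C2CCNCC(c3ccccc3)C2=C1	inactive	fixed
cis-DHX	OC1=C(O)C=C2CC[C@H]3NCc4ccccc4[C@H]3C2=C1	inactive	fixed
(-)-DHX	OC1=C(O)C=C2CC[C@@H]3NCc4ccccc4[C@H]3C2=C1	inactive	fixed
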