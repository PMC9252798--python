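substrate_inchikey	product_smiles	reaction_name	enzymes
WQZGKKKJIJFFOK-UHFFFAOYSA-N	O=P(O)(O)OCC1OC(O)C(O)C(O)C1O	glucose phosphorylation	Hexokinase
NBSCHQHZLSJFNQ-UHFFFAOYSA-N	O=C(COP(=O)(O)O)C(O)C(O)C(O)CO	glucose-6-phosphate isomerization	Glucose-6-phosphate isomerase
JVTAAEKCZFNVCJ-UHFFFAOYSA-N	CC(=O)C(=O)O	lactate oxidation	Lactate dehydrogenase
LCTONWCANYUPML-UHFFFAOYSA-N	CC(O)C(=O)O	pyruvate reduction	Lactate dehydrogenase
QNAYBMKLOCPYGJ-UHFFFAOYSA-N	CC(=O)C(=O)O	alanine transamination	Alanine aminotransferase
WHUUTDBJXJRKMK-UHFFFAOYSA-N	O=C(O)CCC(=O)C(=O)O	glutamate oxidative deamination	Glutamate dehydrogenase
CKLJMWTZIZZHCS-UHFFFAOYSA-N	O=C(O)CC(=O)C(=O)O	aspartate transamination	Aspartate aminotransferase
DHMQDGOQFOQNFH-UHFFFAOYSA-N	NC(CO)C(=O)O	glycine hydroxymethylation	Serine hydroxymethyltransferase
MTCFGRXMJLQNBG-UHFFFAOYSA-N	CC(=O)C(=O)O	serine dehydration	Serine dehydratase
KDYFGRWQOYBRFD-UHFFFAOYSA-N	O=C(O)/C=C/C(=O)O	succinate oxidation	Succinate dehydrogenase
VZCYOOQTPOCHFL-OWOJBTEDSA-N	O=C(O)CC(O)C(=O)O	fumarate hydration	Fumarase
BJEPYKJPYRNKOW-UHFFFAOYSA-N	O=C(O)CC(=O)C(=O)O	malate oxidation	Malate dehydrogenase
KRKNYBCHXYNGOX-UHFFFAOYSA-N	O=C(O)CC(C(=O)O)C(O)C(=O)O	citrate isomerization	Aconitase
PEDCQBHIVMGVHV-UHFFFAOYSA-N	O=P(O)(O)OCC(O)CO	glycerol phosphorylation	Glycerol kinase
OEYIOHPDSNJKLS-UHFFFAOYSA-N	C[N+](C)(C)CC=O	choline oxidation	Choline dehydrogenase
COLNVLDHVKWLRT-UHFFFAOYSA-N	NC(Cc1ccc(O)cc1)C(=O)O	phenylalanine hydroxylation	Phenylalanine hydroxylase
OUYCCCASQSFEME-UHFFFAOYSA-N	NC(Cc1ccc(O)c(O)c1)C(=O)O	tyrosine hydroxylation	Tyrosine hydroxylase
QIVBCDIJIAJPQS-UHFFFAOYSA-N	NCCc1c[nH]c2ccccc12;O=C=O	tryptophan decarboxylation	Aromatic L-amino acid decarboxylase
WHUUTDBJXJRKMK-UHFFFAOYSA-N	NCCCC(=O)O;O=C=O	glutamate decarboxylation	Glutamate decarboxylase
BTCSSZJGUNDROE-UHFFFAOYSA-N	O=CCCC(=O)O	GABA transamination	GABA transaminase
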