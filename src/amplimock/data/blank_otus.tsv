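sample	accession	species	reads	identity	coverage
blank	AF152044	Sphaerium striatinum	63	99	100
blank	AB365642	Lophopodella carteri	1	99	100
blank	AB365626	Plumatella emarginata	1	99	100
blank	GQ343301	Plumatella emarginata	1	95	100
blank	AF152044	Sphaerium striatinum	1	94	100
blank	AB365641	Asajirella gelatinosa	1	94	97
blank	AF499051	Synchaeta pectinata	1	89	75
blank	AF325131	Asplanchna sieboldi	1	87	79
blank	AF499051	Synchaeta pectinata	1	87	75
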