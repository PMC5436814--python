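sample	accession	species	reads	identity	coverage
MOL16S_tank_A	AF152045	Sphaerium striatinum	25707	98-99	100
MOL16S_tank_A	KP052744	Dreissena polymorpha	3037	100	100
MOL16S_tank_A	AF038996	Dreissena rostriformis	235	100	100
MOL16S_tank_A	KF889403	Ferrissia fragilis	218	100	100
MOL16S_tank_A	AY957830	Pisidium casertanum	132	99	100
MOL16S_tank_A	AB365626	Plumatella emarginata	117	100	100
MOL16S_tank_A	DQ459934	Pristina aequiseta	74	97-99	100
MOL16S_tank_A	JN681057	Plumatella emarginata	56	100	100
MOL16S_tank_A	AY957811	Pisidium compressum	52	99	100
MOL16S_tank_A	AF152044	Sphaerium striatinum	10	98	100
MOL16S_tank_B	AF152045	Sphaerium striatinum	21806	99	100
MOL16S_tank_B	KP052744	Dreissena polymorpha	1286	100	100
MOL16S_tank_B	JX099457	Dreissena rostriformis	222	100	100
MOL16S_tank_B	KC429295	Sphaerium nucleus	35	100	100
MOL16S_tank_B	JN681057	Plumatella emarginata	29	100	100
MOL16S_tank_B	GQ355403	Chaetogaster diaphanus	25	99	100
MOL16S_tank_B	KX594326	Homo sapiens	7	100	100
MOL16S_tank_B	AB365626	Plumatella emarginata	5	100	100
SPH16S_tank_A	AF152045	Sphaerium striatinum	240165	99	100
SPH16S_tank_A	AF152044	Sphaerium striatinum	416	98	98
SPH16S_tank_A	AY957830	Pisidium casertanum	215	99	100
SPH16S_tank_A	KC429295	Sphaerium nucleus	68	98	100
SPH16S_tank_B	AF152045	Sphaerium striatinum	217725	99	100
SPH16S_tank_B	KC429295	Sphaerium nucleus	48	100	100
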