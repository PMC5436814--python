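community	species	reads
1	Sphaerium similie	108760
1	Sphaerium corneum	551
1	Pisidium compressum	17
2	Sphaerium similie	1461
2	Sphaerium corneum	16
2	Pisidium compressum	100190
4	Sphaerium similie	500
4	Sphaerium corneum	82990
4	Pisidium compressum	6502
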