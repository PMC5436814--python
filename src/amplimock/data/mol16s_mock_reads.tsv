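community	species	reads
1	Sphaerium similie	138075
1	Dreissena rostriformis	85010
1	Sander vitreus	13
1	Sphaerium corneum	1385
1	Pisidium compressum	195
1	Mytilopsis leucophaeata	23002
1	Dreissena polymorpha	59973
1	Potamopyrgus antipodarum	5594
1	Gillia altilis	6235
1	Cipangopaludina chinensis	711
1	Melanoides tuberculata	99
2	Sphaerium similie	3745
2	Dreissena rostriformis	2174
2	Sander vitreus	0
2	Sphaerium corneum	42
2	Pisidium compressum	149359
2	Mytilopsis leucophaeata	2536
2	Dreissena polymorpha	5166
2	Potamopyrgus antipodarum	565
2	Gillia altilis	783
2	Cipangopaludina chinensis	9513
2	Melanoides tuberculata	12
3	Sphaerium similie	885
3	Dreissena rostriformis	341
3	Sander vitreus	0
3	Sphaerium corneum	112573
3	Pisidium compressum	15359
3	Mytilopsis leucophaeata	800
3	Dreissena polymorpha	2686
3	Potamopyrgus antipodarum	209
3	Gillia altilis	31795
3	Cipangopaludina chinensis	2654
3	Melanoides tuberculata	13
4	Sphaerium similie	773
4	Dreissena rostriformis	244
4	Sander vitreus	2679
4	Sphaerium corneum	116994
4	Pisidium compressum	17620
4	Mytilopsis leucophaeata	1794
4	Dreissena polymorpha	4872
4	Potamopyrgus antipodarum	43807
4	Gillia altilis	67309
4	Cipangopaludina chinensis	5921
4	Melanoides tuberculata	84
5	Sphaerium similie	30
5	Dreissena rostriformis	163825
5	Sander vitreus	63
5	Sphaerium corneum	2199
5	Pisidium compressum	331
5	Mytilopsis leucophaeata	246
5	Dreissena polymorpha	33459
5	Potamopyrgus antipodarum	3752
5	Gillia altilis	4494
5	Cipangopaludina chinensis	536
5	Melanoides tuberculata	26
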