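community	species	copies
1	Sphaerium similie	9090
1	Dreissena rostriformis	1818
1	Sander vitreus	363
1	Sphaerium corneum	72
1	Pisidium compressum	14
1	Mytilopsis leucophaeata	2272
1	Dreissena polymorpha	1136
1	Potamopyrgus antipodarum	568
1	Gillia altilis	284
1	Cipangopaludina chinensis	142
1	Melanoides tuberculata	18
2	Sphaerium similie	1818
2	Dreissena rostriformis	363
2	Sander vitreus	72
2	Sphaerium corneum	14
2	Pisidium compressum	9090
2	Mytilopsis leucophaeata	1136
2	Dreissena polymorpha	568
2	Potamopyrgus antipodarum	284
2	Gillia altilis	142
2	Cipangopaludina chinensis	2272
2	Melanoides tuberculata	18
3	Sphaerium similie	363
3	Dreissena rostriformis	72
3	Sander vitreus	14
3	Sphaerium corneum	9090
3	Pisidium compressum	1818
3	Mytilopsis leucophaeata	568
3	Dreissena polymorpha	284
3	Potamopyrgus antipodarum	142
3	Gillia altilis	2272
3	Cipangopaludina chinensis	1136
3	Melanoides tuberculata	18
4	Sphaerium similie	72
4	Dreissena rostriformis	14
4	Sander vitreus	9090
4	Sphaerium corneum	1818
4	Pisidium compressum	363
4	Mytilopsis leucophaeata	284
4	Dreissena polymorpha	142
4	Potamopyrgus antipodarum	2272
4	Gillia altilis	1136
4	Cipangopaludina chinensis	568
4	Melanoides tuberculata	18
5	Sphaerium similie	14
5	Dreissena rostriformis	9090
5	Sander vitreus	1818
5	Sphaerium corneum	363
5	Pisidium compressum	72
5	Mytilopsis leucophaeata	142
5	Dreissena polymorpha	2272
5	Potamopyrgus antipodarum	1136
5	Gillia altilis	568
5	Cipangopaludina chinensis	284
5	Melanoides tuberculata	18
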