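sample	species	reads_with_block	reads_without_block
mock_community_3	Sphaerium similie	885	718
mock_community_3	Dreissena rostriformis	341	284
mock_community_3	Sander vitreus	0	2
mock_community_3	Sphaerium corneum	112573	100862
mock_community_3	Pisidium compressum	15359	12823
mock_community_3	Mytilopsis leucophaeata	800	701
mock_community_3	Dreissena polymorpha	2686	1924
mock_community_3	Potamopyrgus antipodarum	209	144
mock_community_3	Gillia altilis	31795	25147
mock_community_3	Cipangopaludina chinensis	2654	2024
mock_community_3	Melanoides tuberculata	13	9
mock_community_4	Sphaerium similie	773	314
mock_community_4	Dreissena rostriformis	244	257
mock_community_4	Sander vitreus	2679	11956
mock_community_4	Sphaerium corneum	116994	54766
mock_community_4	Pisidium compressum	17620	7461
mock_community_4	Mytilopsis leucophaeata	1794	1055
mock_community_4	Dreissena polymorpha	4872	2276
mock_community_4	Potamopyrgus antipodarum	43807	23583
mock_community_4	Gillia altilis	67309	32549
mock_community_4	Cipangopaludina chinensis	5921	2876
mock_community_4	Melanoides tuberculata	84	57
trial_run	Dreissena polymorpha	49883	29488
trial_run	Dreissena rostriformis	2253	1449
trial_run	Sphaerium similie	121	31
trial_run	Cipangopaludina chinensis	0	0
trial_run	Sander vitreus	11929	27159
trial_run	Corbicula fluminea	12078	7164
trial_run	Potamopyrgus antipodarum	19	5
trial_run	Valvata piscinalis	992	205
trial_run	Sphaerium corneum	18	6
trial_run	Mytilopsis leucophaeata	0	0
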