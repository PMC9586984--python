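stratification	cutoff_label	category	n	n_pos
none	ais6	below	5466	524
none	ais6	above	1555	698
three_factor	acp26	below	5614	560
three_factor	acp26	above	1407	662
three_factor	acp28.3	below	5672	575
three_factor	acp28.3	above	1349	647
five_factor	acp25	below	5514	526
five_factor	acp25	above	1507	696
five_factor	acp28.3	below	5652	566
five_factor	acp28.3	above	1369	656
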