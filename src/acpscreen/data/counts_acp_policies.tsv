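stratification	cutoff_label	category	n	n_pos
none	none	total	7021	1222
three_factor	acp50	below	6605	957
three_factor	acp50	above	416	265
five_factor	acp50	below	6539	907
five_factor	acp50	above	482	315
five_factor	acp75	below	6889	1121
five_factor	acp75	above	132	101
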