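stratification	cutoff_label	category	n	n_pos
all	none	total	8440	1593
without_md	none	total	8024	1409
without_md	acp50	below	7504	1091
without_md	acp50	above	520	318
md	none	total	416	184
md	acp50	below	256	60
md	acp50	above	160	124
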