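analysis	tf	position	effect	se	p_value	n	significant_corrected	note
flip_avg	TF		0.584271		0.000356833	33	True	
flip_per_position	TF	0	0.372584		0.0327315	33	False	
flip_per_position	TF	1	0.197741		0.269995	33	False	
flip_per_position	TF	2	0.238735		0.180901	33	False	
flip_per_position	TF	3	0.285556		0.107204	33	False	
flip_per_position	TF	4	-0.0292083		0.871815	33	False	
flip_per_position	TF	5	0.265208		0.135799	33	False	
flip_per_position	TF	6	0.168193		0.349463	33	False	
flip_per_position	TF	7	0.376562		0.0307734	33	False	
flip_per_position	TF	8	0.396033		0.0225188	33	False	
flip_per_position	TF	9	0.376187		0.0309535	33	False	
bubble_wilcoxon	TF		0.053114		0.848195	50	False	
bubble_ols	TF		-0.0238242	0.0707768	0.737976	50	False	covariate
bubble_ols	TF		-0.0683465	0.085925	0.433061	31	False	exclude_strong
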