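cluster_id	region	k	x	y	z	sd_x	sd_y	sd_z	validated
37	Inferior parietal lobule L	7	-46	-48	51	7.7	3.9	6.3	1
6	Superior temporal gyrus R	7	45	-60	43	4.5	6.6	9.0	0
33	Angular gyrus R	9	54	-49	22	5.9	6.2	5.5	0
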