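replicon	size_bp	gc_percent	coding_density_percent	n_cds	mean_cds_length_nt
Chromosome	3137147	70.8	84.8	2959	899
P1	432699	69.81	86	383	971
P2	424524	63.89	83.8	523	679
P3	231600	62.97	83.7	282	687
P4	72036	60.44	80.2	70	825
P5	54602	61.87	74.9	79	511
P6	53428	54.72	74.1	44	900
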