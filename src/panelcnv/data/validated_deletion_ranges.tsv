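patient	gene	reported_zygosity	region	ratio_min	ratio_max	dispersion_min	dispersion_max
1	RPS19	heterozygous	promoter-exon5	0.32	0.38	0.0016	0.0039
2	RPS19	heterozygous	promoter-exon5	0.28	0.40	0.0012	0.0088
3	RPS19	heterozygous	promoter-exon5	0.27	0.33	0.002	0.019
4	RPL5	heterozygous	promoter-exon7	0.20	0.35	0.02	0.26
5	RPL11	heterozygous	promoter-exon6	0.30	0.34	0.005	0.0096
6	RBM8A	heterozygous	promoter-exon6	0.31	0.34	0.001	0.011
7	RBM8A	heterozygous	promoter-exon6	0.31	0.35	0.011	0.015
8	GATA2	heterozygous	promoter-exon5	0.30	0.39	0.002	0.008
9	FANCA	homozygous	promoter-exon5	0.002	0.004	0.011	0.067
10	PARN	heterozygous	exon15-exon18	0.32	0.39	0.003	0.031
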