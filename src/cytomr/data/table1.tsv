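biomarker	chromosome	position	variant_id	igap_effect_allele	biomarker_effect_allele	eaf	variance_explained_pct
IL-18	2	32489851	rs385076	C	C	0.34	2.65
IL-18	11	112085316	rs2250417	T	T	0.48	0.50
IL-1ra	2	113834820	rs13386602	A	A	0.44	0.83
IL-1ra	2	113832333	rs6743376	A	A	0.43	0.83
IL-1ra	2	113874467	rs4251961	T	T	0.32	0.29
IL-6	14	52083080	rs1008924	A	A	0.507	0.62
IL-6	1	154426264	rs4129267	T	A	0.41	0.31
IL-6	9	136142355	rs643434	G	G	0.742	2.30
ESR	1	207803021	rs11803956	T	T	0.752	0.88
ESR	16	78019687	rs11861089	C	T	0.694	0.57
ESR	1	207739127	rs3886100	A	A	0.772	0.89
ESR	11	5306509	rs4910742	G	A	0.934	0.65
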