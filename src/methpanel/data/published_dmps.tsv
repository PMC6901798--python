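probe_id	symbol	logFC	adj_p
cg26521404	HOXA9	1.41	7.07E-24
cg01354473	HOXA9	1.12	6.87E-23
cg25720804	TLX3	1.42	8.39E-23
cg15540820	EOMES	1.04	2.58E-20
cg22660578	LHX1	1.10	3.78E-20
cg01381846	HOXA9	1.01	4.57E-20
cg12374721	PRAC1	1.17	4.57E-20
cg08089301	HOXB4	1.55	6.89E-20
cg23290344	NEFM	1.28	7.04E-20
cg07533148	TRIM58	1.54	7.04E-20
cg12880658	CDO1	1.29	7.96E-20
cg19456540	SIX6	1.42	2.06E-19
cg13323752	SLC2A14	1.34	2.31E-19
cg04534765	GALR1	1.23	2.50E-19
cg08118311	SALL3	1.19	2.67E-19
cg02164046	SST	1.02	2.92E-19
cg14859460	GRM6	1.09	3.29E-19
cg02008154	TBX20	1.00	3.96E-19
cg18952647	BNC1	1.30	4.06E-19
cg07778029	HOXA9	1.05	4.13E-19
cg20959866	AJAP1	1.05	1.32E-18
cg22471346	GAS7	1.36	2.02E-18
cg14991487	HOXD9	1.21	4.14E-18
cg22881914	NID2	1.42	4.55E-18
cg24423088	KRTAP8-1	-1.07	4.72E-18
cg23432345	HOXA7	1.20	4.72E-18
cg06760035	HOXB4	1.40	5.67E-18
cg18722841	PHOX2A	1.04	5.68E-18
cg15191648	SALL3	1.04	6.75E-18
cg04048259	EDN3	1.10	1.32E-17
cg17525406	AJAP1	1.22	1.90E-17
cg04490714	SLC6A2	1.03	3.67E-17
cg01009664	TRH	1.08	4.21E-17
cg25875213	ZNF781	1.37	1.05E-16
cg01295203	PRDM14	1.04	1.28E-16
cg14458834	HOXB4	1.32	1.80E-16
cg07307078	TUBB6	1.07	3.09E-16
cg12680609	ZFP41	1.02	5.88E-16
cg06151165	VSX1	1.07	6.28E-16
cg05436658	PRKCB	1.29	1.00E-15
cg17619823	ADRB3	1.09	1.85E-15
cg26963271	PDE4B	1.04	2.25E-15
cg21529533	HLA-G	1.06	3.08E-15
cg10303487	DPYS	1.13	3.28E-15
cg25691167	FERD3L	1.14	3.31E-15
cg26721264	GALR1	1.05	3.40E-15
cg21546671	HOXB4	1.16	3.76E-15
cg25574024	NA	1.02	4.55E-15
cg15520279	HOXD8	1.04	1.38E-14
cg00949442	ABCA3	1.02	2.37E-14
cg09516965	PTGDR	1.26	2.91E-14
cg16731240	ZNF577	1.04	3.74E-14
cg10883303	HOXA13	1.03	4.78E-14
cg13912117	ADCY8	1.05	5.27E-14
cg00848728	DAB1	1.09	5.27E-14
cg21790626	ZNF154	1.13	1.20E-13
cg01805540	CACNB2	1.01	3.98E-12
cg09229912	CUX2	1.06	4.84E-12
cg18349835	VIPR2	1.10	6.70E-12
cg00062776	TULP2	-1.00	2.08E-11
cg19332710	RIMS4	1.00	1.67E-10
cg02723533	CCND1	-1.04	2.70E-10
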