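name	formula	reported_mass	kegg_id	compound_class	validation_level	log2fc_a	log2fc_b	vip_c1_a	vip_c1_b	vip_c2_a	vip_c2_b	p_raw_a	p_raw_b
Citrulline	C6H13N3O3	175.09587	C00327	Carboxylic acids and derivatives	1	-0.15	-0.2	1.22	1.56	1.13	1.32	0.137	0.034
Creatinine	C4H7N3O	113.05889	C00791	Azoline	1	-0.21	-0.11	2.6	1.85	2.37	1.47	0.001	0.011
(L)-tryptophan	C11H12N2O2	204.0902	C00078	Indoles and derivatives	1	-0.09	-0.22	1.18	2.08	1.08	1.64	0.148	0.004
LysoPE(18:1)	C23H46NO7P	479.30081		Glycerophosphoethanolamine	3	-0.55	-0.38	1.74	1.49	1.65	1.21	0.028	0.044
LysoPE(18:2)	C23H44NO7P	477.28562		Glycerophosphoethanolamine	3	-0.55	-0.45	1.74	1.84	1.66	1.48	0.029	0.011
LysoPE(22:4)	C27H48NO7P	529.31598		Glycerophosphoethanolamine	3	-0.4	-0.4	1.15	1.58	1.05	1.39	0.161	0.031
LysoPC(P-16:0)	C24H50NO6P	479.33765	C04230	Glycerophosphocholine	3	-0.2	-0.25	1.2	1.49	1.19	1.34	0.133	0.033
LysoPC(P-18:0)	C26H54NO6P	507.3682	C04230	Glycerophosphocholine	3	-0.23	-0.26	1.34	1.58	1.15	1.29	0.142	0.044
LysoPC(P-18:1)	C26H52NO6P	505.35284	C04230	Glycerophosphocholine	3	-0.25	-0.25	1.27	1.82	1.26	1.26	0.099	0.032
PC(44:12)	C52H80NO8P	877.56643	C00157	Glycerophosphocholine	3	-0.25	-0.24	1.18	1.71	1.17	1.44	0.118	0.012
LysoPC(20:1)	C28H56NO7P	549.3787	C04230	Glycerophosphocholine	3	-0.26	-0.37	1.43	1.75	1.14	1.38	0.147	0.019
LysoPC(20:0)	C28H58NO7P	551.39427	C04230	Glycerophosphocholine	3	-0.31	-0.34	1.24	1.57	1.34	1.42	0.079	0.017
PE(36:5)	C41H72NO8P	737.49806	C00350	Glycerophosphoethanolamine	3	-0.3	-0.29	1.5	1.3	1.4	1.03	0.066	0.08
PC(35:5)	C43H76NO8P	765.53003	C00157	Glycerophosphocholine	3	-0.24	-0.54	1.41	1.21	1.3	1.08	0.082	0.106
PC(18:1/18:1)	C44H84NO8P	785.59391	C00157	Glycerophosphocholine	3	-0.12	-0.07	1.77	1.27	1.62	1.11	0.026	0.088
PC(18:0/18:3)	C44H82NO8P	783.57697	C00157	Glycerophosphocholine	3	-0.07	-0.08	1.21	1.62	1.24	1.35	0.139	0.027
Tiglylcarnitine	C12H21NO4	243.14724		Fatty Acyl	3	-0.4	-0.46	1.87	2.15	1.81	1.77	0.018	0.003
2(R)-HOT	C18H30O3	294.22165	C16342	Lineolic acids and derivatives	3	-0.13	-0.17	1.98	2.32	1.8	1.94	0.013	0.001
GPC(14:0)	C46H78NO7P	787.54959		Glycerophosphocholine	3	-0.26	-0.1	2.25	1.16	2.06	1.06	0.003	0.12
Gamma-Linolenic acid	C18H30O2	278.22449	C06426	Lineolic acids and derivatives	2	-0.36	-0.39	1.25	1.51	1.16	1.19	0.127	0.041
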