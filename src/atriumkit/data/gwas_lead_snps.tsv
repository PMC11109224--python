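trait	chr	bp	rsid	ea	oa	eaf	beta	se	p	nearest_gene
LAmax	6	31294375	rs9265346	G	A	0.33	0.045	0.007	1.10E-09	HLA-B
LAmax	6	79554193	rs6926537	T	A	0.512	-0.039	0.007	9.10E-09	IRAK1BP1
LAmax	6	107433645	rs60237682	T	C	0.683	-0.041	0.007	3.80E-08	BEND3
LAmax	12	66343400	rs1038196	G	C	0.486	0.039	0.007	1.10E-08	HMGA2
LAmax	19	46213416	rs62111731	A	G	0.479	0.042	0.007	7.10E-10	FBXO46
LAmax_indexed	2	179650954	rs6715901	G	A	0.507	-0.043	0.008	1.20E-08	TTN
LAmax_indexed	4	111665783	rs2634073	T	C	0.166	0.057	0.01	2.00E-08	PITX2
LAmax_indexed	5	32831670	rs13154066	T	C	0.402	-0.05	0.008	6.60E-11	NPR3
LAmax_indexed	6	31229203	rs9264391	G	A	0.893	-0.089	0.014	9.30E-11	HLA-C
LAmax_indexed	6	107442277	rs9480737	A	G	0.682	-0.05	0.008	8.80E-10	BEND3
LAmax_indexed	19	46166806	rs140153691	T	TGC	0.639	-0.047	0.008	4.10E-09	GIPR
LAmax_indexed	22	26156505	rs133873	T	A	0.775	-0.055	0.009	9.60E-10	MYO18B
LAEF	1	51322205	rs79948214	A	G	0.984	0.161	0.029	4.70E-08	FAF1
LAEF	1	116310967	rs4074536	T	C	0.702	-0.052	0.008	7.80E-11	CASQ2
LAEF	14	23874117	rs440466	T	C	0.622	0.056	0.008	7.30E-14	MYH6
LAEF	22	26159289	rs133885	G	A	0.548	0.046	0.007	3.60E-10	MYO18B
LAmin	6	31294375	rs9265346	G	A	0.33	0.044	0.007	8.30E-09	HLA-B
LAmin	6	79518638	rs35790661	C	CCA	0.63	-0.043	0.007	4.40E-09	IRAK1BP1
LAmin	6	107442277	rs9480737	A	G	0.682	-0.041	0.007	3.10E-08	BEND3
LAmin	10	92681480	rs780162510	C	ATAC	0.49	0.04	0.007	2.20E-08	ANKRD1
LAmin	11	65336819	rs3782089	C	T	0.928	0.074	0.013	4.70E-08	SSSCA1
LAmin	15	99248018	rs4966014	C	T	0.3	0.045	0.008	4.20E-09	IGF1R
LAmin	19	46315357		A	TA	0.476	0.047	0.007	1.20E-11	RSPH6A
LAmin	22	26164079	rs133902	C	T	0.56	-0.041	0.007	4.30E-09	MYO18B
LAmin_indexed	2	3912741	rs56289263	C	T	0.938	-0.093	0.017	4.40E-08	DCDC2C
LAmin_indexed	2	179650954	rs6715901	G	A	0.507	-0.041	0.007	4.50E-08	TTN
LAmin_indexed	4	24289655	rs1533093	C	T	0.862	-0.062	0.011	3.80E-08	DHX15
LAmin_indexed	4	111665783	rs2634073	T	C	0.166	0.057	0.01	1.20E-08	PITX2
LAmin_indexed	5	32831670	rs13154066	T	C	0.402	-0.043	0.008	1.40E-08	NPR3
LAmin_indexed	6	31294375	rs9265346	G	A	0.33	0.047	0.008	1.00E-08	HLA-B
LAmin_indexed	6	107442277	rs9480737	A	G	0.682	-0.049	0.008	1.00E-09	BEND3
LAmin_indexed	8	97223162	rs35216833	C	T	0.456	0.042	0.007	1.00E-08	UQCRB
LAmin_indexed	10	92586289	rs112343361	A	ACT	0.497	-0.046	0.008	1.80E-09	HTR7
LAmin_indexed	15	99248018	rs4966014	C	T	0.3	0.047	0.008	1.80E-08	IGF1R
LAmin_indexed	17	45097337	rs8078336	G	T	0.965	-0.137	0.025	2.70E-08	GOSR2
LAmin_indexed	19	46292259	rs7246377	G	A	0.534	-0.049	0.007	2.80E-11	DMWD
LAmin_indexed	22	26156512	rs133874	A	G	0.773	-0.061	0.009	6.80E-12	MYO18B
LASV	6	31225196	rs199610865	T	TA	0.853	-0.055	0.01	2.90E-08	HLA-C
LASV	14	23869029	rs376439	A	G	0.606	0.045	0.007	2.70E-10	MYH6
LASV_indexed	6	31225196	rs199610865	T	TA	0.853	-0.067	0.011	4.70E-10	HLA-C
LASV_indexed	9	136138765	rs8176685	G	CGCCCACCACTAG	0.82	-0.059	0.01	3.20E-09	OBP2B
LASV_indexed	14	23869029	rs376439	A	G	0.606	0.048	0.008	8.10E-10	MYH6
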