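pufa	gene	rsid	chr	pos	ea	nea	eaf	beta	se	pval	ve_percent	f_stat
ALA	FEN1	rs423341	11	61316837	T	C	0.16	-0.0118	0.0016	9.72E-14	0.342	30
ALA	C11orf9	rs198464	11	61278197	A	G	0.50	-0.0057	0.0009	2.48E-11	0.148	13
ALA	C11orf10	rs740006	11	61314444	T	C	0.90	0.0163	0.0025	1.32E-10	0.440	39
ALA	C11orf9	rs17762402	11	61309777	A	G	0.07	-0.0186	0.0029	1.56E-10	0.411	37
DHA	ELOVL2	rs2236212	6	10995015	C	G	0.41	-0.1132	0.0141	1.26E-15	0.646	58
DPA	ELOVL2	rs3734398	6	10982973	T	C	0.57	-0.0404	0.0029	9.61E-44	2.667	243
DPA	FEN1	rs423341	11	61560261	T	C	0.16	0.0554	0.0052	1.40E-26	2.750	251
DPA	C11orf10	rs740006	11	61557868	T	C	0.90	-0.0764	0.0079	4.50E-22	3.502	322
DPA	FADS3	rs7394871	11	61652514	A	C	0.05	-0.0637	0.0078	3.56E-16	1.285	115
DPA	FADS2	rs498793	11	61624705	T	C	0.43	0.0307	0.0038	5.84E-16	1.540	139
DPA	SYCP2L	rs12199131	6	10932569	A	G	0.26	0.0267	0.0033	7.69E-16	0.914	82
DPA	RAB3IL1	rs174472	11	61671956	A	G	0.58	0.0274	0.0037	5.74E-14	1.219	109
DPA	C11orf9	rs17762402	11	61553201	A	G	0.06	0.0805	0.0109	1.42E-13	2.437	221
DPA	SYCP2L	rs6928281	6	10908917	T	G	0.72	0.0226	0.0032	8.04E-13	0.686	61
DPA	C11orf9	rs198464	11	61521621	A	G	0.49	0.0191	0.0028	7.47E-12	0.608	54
DPA	FADS2	rs17156442	11	61614023	T	C	0.05	-0.0513	0.0077	2.09E-11	0.833	74
DPA	BEST1	rs1109748	11	61722645	A	C	0.07	-0.0400	0.0068	5.09E-09	0.694	62
DPA	ELOVL2	rs6936315	6	11035972	T	C	0.84	0.0244	0.0043	1.34E-08	0.533	48
DPA	FTH1	rs10792320	11	61746291	A	C	0.65	0.0160	0.0030	8.49E-08	0.388	35
DPA	BEST1	rs2727266	11	61704334	A	G	0.93	0.0308	0.0058	8.86E-08	0.412	37
EPA	FADS3	rs7394871	11	61652514	A	C	0.05	-0.0912	0.0128	1.13E-12	0.494	44
EPA	ELOVL2	rs3798713	6	11008622	C	G	0.42	0.0350	0.0050	1.93E-12	0.373	33
EPA	BEST1	rs1109748	11	61722645	A	C	0.07	-0.0535	0.0092	5.46E-09	0.233	21
EPA	FEN1	rs423341	11	61560261	T	C	0.16	0.0440	0.0081	4.59E-08	0.325	29
EPA	FADS2	rs498793	11	61624705	T	C	0.43	0.0351	0.0064	5.11E-08	0.377	34
EPA	MAT2B	rs1145652	5	164764087	A	G	0.87	0.0356	0.0066	8.39E-08	0.179	16
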