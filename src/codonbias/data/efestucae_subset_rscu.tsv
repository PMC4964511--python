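amino_acid	codon	rscu_high	n_high	rscu_low	n_low	optimal_published
F	UUU	0.41	1246	0.97	4176	0
F	UUC	1.59	4874	1.03	4414	1
L	UUA	0.03	86	0.54	2081	0
L	UUG	0.55	1375	1.27	4893	0
L	CUU	0.29	744	1.22	4713	0
L	CUC	2.90	7320	1.10	4257	1
L	CUA	0.14	358	0.71	2725	0
L	CUG	2.08	5252	1.16	4456	1
I	AUU	0.57	1339	1.20	4799	0
I	AUC	2.24	5277	1.13	4511	1
I	AUA	0.19	442	0.68	2704	0
M	AUG	1.00	3940	1.00	5668	0
V	GUU	0.35	1025	1.18	4457	0
V	GUC	2.39	7011	1.21	4561	1
V	GUA	0.11	322	0.63	2379	0
V	GUG	1.16	3396	0.97	3649	1
Y	UAU	0.29	651	1.03	3182	0
Y	UAC	1.71	3910	0.97	2979	1
S	AGU	0.24	488	0.76	3234	0
S	AGC	1.61	3266	1.05	4495	1
H	CAU	0.42	875	1.11	3946	0
H	CAC	1.58	3322	0.89	3180	1
Q	CAA	0.42	1184	1.07	6735	0
Q	CAG	1.58	4457	0.93	5867	1
N	AAU	0.30	808	0.98	4824	0
N	AAC	1.70	4557	1.02	4978	1
K	AAA	0.29	1091	0.94	5763	0
K	AAG	1.71	6306	1.06	6539	1
D	GAU	0.40	1941	1.03	8086	0
D	GAC	1.60	7765	0.97	7678	1
E	GAA	0.39	1802	1.03	8278	0
E	GAG	1.61	7396	0.97	7846	1
S	UCU	0.40	818	1.22	5215	0
S	UCC	1.96	3989	0.89	3811	1
S	UCA	0.31	635	1.17	5018	0
S	UCG	1.48	2998	0.91	3878	1
P	CCU	0.43	1030	1.10	4937	0
P	CCC	2.13	5100	0.81	3633	1
P	CCA	0.32	763	1.27	5704	0
P	CCG	1.12	2689	0.81	3651	1
T	ACU	0.28	685	1.04	4130	0
T	ACC	1.80	4428	0.91	3615	1
T	ACA	0.38	941	1.20	4774	0
T	ACG	1.54	3796	0.86	3422	1
A	GCU	0.38	1665	1.14	6365	0
A	GCC	2.29	9960	1.05	5840	1
A	GCA	0.34	1462	1.10	6141	0
A	GCG	0.99	4333	0.70	3903	1
C	UGU	0.29	322	0.95	1626	0
C	UGC	1.71	1869	1.05	1790	1
W	UGG	1.00	2561	1.00	3365	0
G	GGU	0.39	1322	0.96	4175	0
G	GGC	2.55	8641	1.35	5864	1
G	GGA	0.37	1263	1.03	4480	0
G	GGG	0.69	2353	0.65	2813	0
R	AGA	0.45	825	1.17	3566	0
R	AGG	1.29	2390	0.79	2427	1
R	CGU	0.37	680	0.82	2510	0
R	CGC	2.34	4329	1.02	3113	1
R	CGA	0.50	932	1.41	4306	0
R	CGG	1.05	1934	0.80	2440	1
*	UAA	0.62	101	0.79	169	0
*	UAG	0.92	150	0.74	158	0
*	UGA	1.47	240	1.48	317	0
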