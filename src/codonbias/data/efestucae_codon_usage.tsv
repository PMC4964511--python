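amino_acid	codon	total_count	rscu_published
F	UUU	31361	0.71
F	UUC	53807	1.28
L	UUA	8539	0.22
L	UUG	39289	1.05
L	CUU	32567	0.86
L	CUC	63009	1.84
L	CUA	15908	0.42
L	CUG	57144	1.61
I	AUU	36953	0.97
I	AUC	56383	1.61
I	AUA	14980	0.42
M	AUG	56564	1.00
V	GUU	33011	0.83
V	GUC	63583	1.69
V	GUA	15230	0.39
V	GUG	41264	1.08
Y	UAU	21165	0.68
Y	UAC	39027	1.29
C	UGU	10231	0.59
C	UGC	20393	1.25
H	CAU	27393	0.81
H	CAC	36289	1.16
Q	CAA	44072	0.80
Q	CAG	59569	1.19
N	AAU	32251	0.70
N	AAC	55829	1.29
K	AAA	37695	0.63
K	AAG	80172	1.37
D	GAU	60666	0.79
D	GAC	87756	1.21
E	GAA	60978	0.76
E	GAG	89320	1.23
S	UCU	33326	0.87
S	UCC	44291	1.33
S	UCA	30242	0.76
S	UCG	39274	1.14
P	CCU	35400	0.86
P	CCC	49710	1.37
P	CCA	35372	0.83
P	CCG	36167	0.93
T	ACU	27362	0.71
T	ACC	46502	1.30
T	ACA	31612	0.81
T	ACG	40791	1.17
A	GCU	49281	0.84
A	GCC	88269	1.58
A	GCA	44142	0.75
A	GCG	45406	0.83
*	UGA	2445	1.39
*	UAA	1271	0.74
*	UAG	1529	0.87
W	UGG	34101	0.94
R	CGU	20731	0.73
R	CGC	40880	1.55
R	CGA	33836	1.13
R	CGG	23806	0.86
R	AGA	24225	0.84
R	AGG	23489	0.89
G	GGU	35358	0.75
G	GGC	79015	1.79
G	GGA	35677	0.78
G	GGG	28001	0.67
S	AGU	21367	0.57
S	AGC	46172	1.32
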