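variant	cdna	clinvar_class	diagnosis	rarity	tested	control	sift	polyphen2	cadd	revel	alphamissense	foldx_ddg	insilico_printed	induction	expression_ratio	expression_reduced	autophos_t899	dimerisation	eif2a_phos_pct	rescue_gcn2ib	context_null_second_allele	classification
P15L	44C>T	VUS	PAH (Het)	rare	true	false	T	0	22.6	0.133	0.0834	0.23	Benign	yes	0.83	false	yes	.	.	.	false	Benign
Y34C	145-2A>G	benign/likely-benign	PVOD (C Het)	rare	true	false	T	0.999	32	0.634	0.4589	3.79	Misfolded	yes	0.21	true	yes	.	.	.	true	Destabilised
D74N	220G>A	VUS	PAH (Het)	rare	false	false	NT	0.954	28	0.166	0.1726	0.38	Benign	.	.	.	.	.	.	.	false	.
V121M	361G>A	VUS	PVOD (C Het)	rare	false	false	T	1	33	0.467	0.7125	-1.04	Benign	.	.	.	.	.	.	.	false	.
R360C	1078C>T	VUS	PCH	rare	false	false	NT	0.999	26.3	0.566	0.083	1.68	Uncertain	.	.	.	.	.	.	.	false	.
I441L	1321A>C	benign/likely-benign	PCH	common	false	false	T	0.001	16.9	0.075	0.0839	-0.70	Benign	.	.	.	.	.	.	.	false	.
L489P	1466C>T	VUS	PAH	rare	false	false	NT	1	29	0.895	0.9737	7.89	Misfolded	.	.	.	.	.	.	.	false	.
E556G	1667A>G	benign/likely-benign	PCH	common	false	false	T	0	22.5	0.088	0.0523	0.63	Benign	.	.	.	.	.	.	.	false	.
I565T	1694T>C	VUS	PCH	rare	false	false	T	0.835	22.2	0.307	0.2246	-0.36	Benign	.	.	.	.	.	.	.	false	.
R585Q	1754G>A	pathogenic/likely-pathogenic	PVOD; PCH	rare	true	false	NT	1	32	0.861	0.9272	2.12	Kinase-deficient	no	1.09	false	yes	yes	32.6	rescued	false	Hypomorphic
G599R	1795G>C	pathogenic/likely-pathogenic	PAH; PCH (Hom)	rare	false	false	NT	1	32	0.952	0.9991	0.83	Kinase-deficient	.	.	.	.	.	.	.	false	.
V607G	1820T>G	pathogenic/likely-pathogenic	PAH (C Het); PCH	rare	true	false	NT	0.998	33	0.557	0.8039	4.73	Misfolded	no	0.71	true	yes	yes	42.8	rescued	false	Hypomorphic
L643R	1928T>G	pathogenic/likely-pathogenic	PVOD; PCH	rare	true	false	NT	0.999	32	0.889	0.9911	9.65	Misfolded	no	0.26	true	no	yes	0	not-rescued	false	Kinase-dead
P674S	2020C>T	benign/likely-benign	PCH	rare	false	false	T	0.029	12.1	0.077	0.0694	-1.45	Benign	.	.	.	.	.	.	.	false	.
I839T	2516T>C	VUS	PAH (Het)	rare	true	false	NT	0.99	29.6	0.781	0.9854	2.90	Benign	yes	0.85	false	yes	.	.	.	false	Benign
A870V	2609C>T	VUS	PVOD (C Het)	rare	true	false	T	1	28.1	0.658	0.9943	0.95	Uncertain	no	1.00	false	no	.	.	.	false	Kinase-dead
D888H	2662G>C	benign/likely-benign	PCH	rare	false	false	NT	0.998	24.8	0.237	0.1005	0.59	Benign	.	.	.	.	.	.	.	false	.
S909R	2727C>G	pathogenic/likely-pathogenic	PAH (Het); PCH	rare	true	false	NT	1	28	0.446	0.9985	5.67	Misfolded	no	0.39	true	no	yes	.	not-rescued	false	Kinase-dead
T943A	2827A>G	VUS	PAH (C Het)	rare	true	false	NT	0.997	25.4	0.464	0.8597	1.54	Benign	yes	1.06	false	yes	.	.	.	false	Benign
R989W	2965C>T	VUS	PVOD	rare	true	false	NT	1	28.9	0.862	0.9838	38.59	Misfolded	no	0.09	true	no	.	.	.	false	Misfolded
R1073L	3218G>T	VUS	PAH	rare	false	false	NT	0.995	32	0.466	0.3374	0.15	Benign	.	.	.	.	.	.	.	false	.
G1109R	3325G>A	pathogenic/likely-pathogenic	PAH (C Het); PCH	rare	true	false	NT	1	32	0.766	0.9856	9.20	Uncertain	no	0.68	false	yes	.	27.2	rescued	false	Hypomorphic
P1115L	3344C>T	pathogenic/likely-pathogenic	PAH; PVOD; IPAH; PCH	rare	true	false	NT	1	29.7	0.702	0.8415	1.46	Uncertain	no	0.76	false	yes	.	12.9	rescued	false	Hypomorphic
A1127V	3380C>T	VUS	PVOD	rare	false	false	T	1	32	0.262	0.6049	6.08	Misfolded	.	.	.	.	.	.	.	false	.
L1148S	3443T>C	VUS	CTD-APAH	rare	true	false	T	1	28.4	0.341	0.2648	1.11	Benign	yes	0.99	false	yes	.	.	.	false	Benign
H1202Y	3604C>T	VUS	PAH (Het)	rare	true	false	T	0.996	26.5	0.716	0.812	-0.44	Benign	yes	0.14	true	yes	.	.	.	false	Benign
H1202L	3605A>T	pathogenic/likely-pathogenic	PAH; PCH (Hom)	rare	true	false	NT	0.998	28.4	0.802	0.9507	3.00	Uncertain	no	0.12	true	yes	.	0	.	false	Misfolded
E1241G	3722A>G	VUS	PAH	rare	false	false	NT	0.971	33	0.342	0.7069	1.50	Benign	.	.	.	.	.	.	.	false	.
L1295R	3884T>G	pathogenic/likely-pathogenic	PAH; PCH (C Het)	rare	true	false	NT	1	28.8	0.814	0.9408	4.89	Misfolded	no	0.10	true	no	.	0	.	false	Misfolded
G1306C	3916G>T	benign/likely-benign	PCH	common	false	false	NT	1	31	0.307	0.2596	2.26	Uncertain	.	.	.	.	.	.	.	false	.
K1336R	4007A>G	benign/likely-benign	PCH	rare	false	false	T	0	15.8	0.063	0.0564	0.14	Benign	.	.	.	.	.	.	.	false	.
V1402L	4204G>T	VUS	IPAH	rare	false	false	T	0.997	24.7	0.285	0.4847	-0.19	Benign	.	.	.	.	.	.	.	false	.
R1549H	4646G>A	VUS	PAH (Het)	rare	false	false	NT	0.998	32	0.318	0.6517	0.30	Benign	.	.	.	.	.	.	.	false	.
L1637P	4910T>C	VUS	PVOD (C Het)	rare	false	false	NT	1	31	0.624	0.9982	5.98	Misfolded	.	.	.	.	.	.	.	false	.
K619R	.	.	engineered kinase-dead control	.	true	true	NT	1	32	0.783	0.9769	0.20	Kinase-deficient	no	1.17	false	no	.	0	not-rescued	false	Kinase-dead
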