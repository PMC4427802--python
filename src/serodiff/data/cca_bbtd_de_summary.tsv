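label	accession	mean_a	sd_a	mean_b	sd_b	printed_p	direction
ABHD11	23200008	1.20	0.4	0.82	0.3	0.002	up
Antioxidized LDL immunoglobulin light chain variable region	62868476	0.88	0.3	0.55	0.3	0.004	up
Fab fragment of nimotuzumab (chain L)	255311843	1.93	0.2	1.72	0.3	0.010	up
Complement factor H	758073	-0.86	0.3	-1.51	0.5	0.001	up
COG7	23957690	-0.50	0.4	-1.23	0.5	<0.001	up
DHDDS	13177736	0.14	0.6	-0.61	0.5	0.005	up
MLH1	4557757	-0.49	0.5	-1.00	0.5	0.004	up
EIF3J	83281438	2.40	0.4	1.95	0.4	0.002	up
FAM19A5	71052198	0.98	0.3	-0.69	0.7	<0.001	up
HBZ	4885397	-0.23	0.3	-0.78	0.4	0.001	up
V4-34	2632200	0.54	0.4	0.20	0.2	0.001	up
Immunoglobulin heavy chain variable region	37694587	1.46	0.4	0.93	0.5	0.003	up
IGK	21669309	1.98	0.3	1.68	0.1	<0.001	up
IL16	119619506	0.15	0.4	-0.36	0.6	0.008	up
KIAA0321	2224583	-0.25	0.8	-1.70	0.9	0.002	up
KIAA0612	34327964	-1.17	0.4	-1.76	0.5	0.006	up
KIAA0896	71891755	0.18	0.6	-0.50	0.6	0.003	up
MAGED4B	29337296	0.33	0.3	-1.17	0.9	0.002	up
NXF3	11545757	0.59	0.4	-0.29	0.5	<0.001	up
PAXBP1	22035565	0.64	0.1	0.39	0.2	0.001	up
LOC390791	310113085	-0.50	0.3	-1.24	0.4	0.002	up
PLEKHO2	33457316	-0.29	0.4	-0.91	0.4	0.001	up
PLEKHM2	26251859	-0.46	0.4	-1.06	0.5	0.002	up
RBAK	13430850	0.17	0.5	-0.96	0.7	<0.001	up
PTPRG	1263069	0.90	0.3	0.54	0.2	<0.001	up
RPS10	3088338	0.99	0.2	0.67	0.1	<0.001	up
NOB1	7661532	-0.81	0.4	-1.26	0.4	0.002	up
VAT1	18379349	0.57	0.4	0.15	0.3	0.003	up
TRAC-1	1911770	0.12	0.3	-0.28	0.2	<0.001	up
Unnamed protein product (10433849)	10433849	1.67	0.5	0.77	0.3	<0.001	up
Unnamed protein product (21752201)	21752201	0.27	0.2	-0.07	0.3	0.001	up
GCAT	7657118	-1.62	0.5	-1.17	0.3	0.002	down
ALB	119626083	1.05	0.3	1.45	0.3	<0.001	down
SERPINA1	1703025	0.84	0.4	1.24	0.3	<0.001	down
A2M	177872	-0.04	0.4	0.52	0.3	<0.001	down
AGT	4261988	0.09	0.6	0.79	0.2	<0.001	down
apo AII	671882	0.04	0.3	0.31	0.2	0.003	down
APOB	105990532	-1.67	0.4	-0.86	0.5	<0.001	down
ARID5B	74136549	0.08	0.5	0.71	0.7	0.006	down
BAZ2	6002480	-0.50	0.9	0.23	0.3	0.005	down
C1orf87	27503780	-0.91	0.4	-0.49	0.3	0.001	down
PDEA	2366987	0.11	0.4	0.73	0.3	<0.001	down
Nucleosome with testis-specific histone variant (chain D)	296863399	-2.56	0.4	-2.04	0.5	0.002	down
C4A	476007827	-0.81	0.7	-0.02	0.3	<0.001	down
DCAF15	78486540	0.87	0.4	1.31	0.2	<0.001	down
FN1	53791223	-0.98	0.5	-0.29	0.4	<0.001	down
FLJ00044	10440418	-1.02	0.4	-0.59	0.2	0.004	down
FLJ16008	119615716	1.79	0.1	1.94	0.2	0.006	down
GNG5	4885287	0.94	0.3	1.24	0.1	<0.001	down
hCG_1817987	119612015	-0.09	0.3	0.36	0.3	<0.001	down
hCG_1981701	119572460	-1.14	0.5	-0.52	0.5	0.002	down
hCG_2008076	119592316	0.05	0.4	0.42	0.2	0.012	down
hCG_2008267	119592800	-0.07	0.4	0.35	0.2	0.001	down
hCG_201157	119576573	0.64	0.3	0.89	0.3	0.009	down
hCG_2020343	119629275	-0.95	0.4	-0.27	0.4	<0.001	down
Hypothetical protein (12224988)	12224988	-1.46	0.5	-0.90	0.4	<0.001	down
FLJ22688	119572924	-0.93	0.6	-0.17	0.4	<0.001	down
LOC286076	119602615	1.19	0.4	1.52	0.2	0.003	down
IgA1	223099	1.84	0.6	2.28	0.3	0.006	down
Immunoglobulin heavy chain variable region (37694587)	37694587	1.48	0.3	1.70	0.1	0.007	down
ITIH1	825681	-0.74	0.4	0.08	0.6	0.001	down
ITIH2	119606784	-1.44	0.5	-0.54	0.4	<0.001	down
KRT1	11935049	-1.12	0.3	-0.56	0.4	<0.001	down
KRT10	307086	-2.40	0.5	-1.50	0.6	<0.001	down
KIAA0366	2224673	-1.45	0.4	-0.61	0.6	<0.001	down
KIAA0920	40788986	1.05	0.3	1.37	0.2	<0.001	down
KIAA1234	6330736	-0.70	0.4	-0.38	0.3	0.007	down
KIAA1529	7959325	1.33	0.3	2.38	0.4	<0.001	down
MAGEB2	222418639	-0.48	0.3	-0.07	0.4	0.001	down
MTDH	119612168	-0.45	0.3	-0.09	0.3	<0.001	down
MUC16	74716283	-0.49	0.5	0.41	0.4	<0.001	down
MYOT	5803106	-0.41	0.5	0.30	0.3	<0.001	down
NPTX1	1438954	1.51	0.3	1.74	0.2	0.010	down
PLG	38051823	1.67	0.3	2.17	0.4	<0.001	down
GALNT2	4758412	-0.99	0.3	-0.50	0.3	<0.001	down
FAM83E	153251792	0.70	0.5	1.33	0.3	0.006	down
LOC100131107	239741331	1.03	0.7	2.07	0.7	0.002	down
RAB-R	4102709	-0.83	0.4	-0.05	0.3	0.002	down
UPF3B	18375528	-2.17	0.5	-0.99	0.6	<0.001	down
RIMBP3	71052030	0.07	0.4	0.69	0.4	<0.001	down
SOCS3	54695958	0.85	0.4	1.23	0.2	0.004	down
TESK1	21886788	-1.65	0.3	-1.07	0.7	0.005	down
TTC34	239741018	-0.54	0.5	0.34	0.3	<0.001	down
TPO	4680721	0.69	0.4	1.15	0.2	<0.001	down
UTY transcript	148733192	-1.43	0.4	-0.88	0.5	0.001	down
Unnamed protein product (34531956)	34531956	0.84	0.3	1.17	0.2	<0.001	down
Unnamed protein product (10435479)	10435479	0.76	0.4	1.15	0.3	0.003	down
Unnamed protein product (194384842)	194384842	1.24	0.3	1.67	0.2	<0.001	down
Unnamed protein product (22760231)	22760231	1.14	0.5	1.77	0.3	<0.001	down
Unnamed protein product (194381130)	194381130	-2.08	0.4	-1.34	0.5	<0.001	down
DBP	455970	0.88	0.5	1.30	0.3	0.007	down
ZNF410	119601547	-0.27	0.4	0.46	0.3	<0.001	down
ZnF_RBZ	4191327	0.03	0.4	0.55	0.4	0.001	down
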