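trait	gene	chrom	pos	ref	alt	af	n_disc	beta_disc	se_disc	p_disc	n_rep	beta_rep	se_rep	p_rep	n_comb	beta_comb	se_comb	p_comb
Lp(a)	LPA	NA	NA	NA	NA	0.075	6696	-0.608	0.031	2.17e-81	2200	-0.729	0.055	6.8e-39	8896	-0.637	0.027	1.53e-117
Vitamin-B12	FUT2	19	49206674	G	A	0.62	6087	0.199	0.019	3.68e-26	NA	NA	NA	NA	NA	NA	NA	NA
Galectin-3	TBPL2	14	55890937	T	A	0.011	6648	-0.460	0.080	9.37e-9	NA	NA	NA	NA	NA	NA	NA	NA
GCSF	ATP2C2	16	84495318	A	C	0.023	6660	0.272	0.055	6.98e-7	2188	-0.037	0.105	0.73	8848	0.206	0.049	2.2e-5
IL4	ATP2C2	16	84495318	A	C	0.023	6660	0.258	0.055	2.48e-6	2188	0.035	0.105	0.74	8846	0.209	0.061	5.91e-4
IFN-gamma	ATP2C2	16	84495318	A	C	0.023	6660	0.255	0.055	3.24e-6	2188	0.060	0.105	0.57	8841	0.051	0.016	1.45e-3
IL6	ATP2C2	16	84495318	A	C	0.023	6660	0.251	0.055	4.58e-6	2188	0.073	0.105	0.49	8848	0.213	0.049	1.16e-5
Endothelin1	FUT2	19	49206674	G	A	0.62	6146	0.086	0.019	5.63e-6	NA	NA	NA	NA	NA	NA	NA	NA
D-dimer	FGL1	8	17726470	A	AT	0.037	6582	0.210	0.046	6.12e-6	NA	NA	NA	NA	NA	NA	NA	NA
IL12	ATP2C2	16	84495318	A	C	0.023	6660	0.245	0.055	8.13e-6	2188	0.042	0.105	0.69	8848	0.201	0.049	3.45e-5
IL17	ATP2C2	16	84495318	A	C	0.023	6660	0.241	0.055	1.12e-5	2188	-0.136	0.105	0.20	8848	0.160	0.049	9.91e-4
Systolic-bp	ATP2C2	16	84495318	A	C	0.023	25764	0.125	0.029	1.25e-5	9355	0.113	0.054	0.037	35119	0.122	0.025	1.31e-6
IFN-gamma	P4HA3	11	73978243	G	A	0.32	6655	0.080	0.019	1.70e-5	2186	-0.036	0.032	0.27	8841	0.051	0.016	1.45e-3
IL17	P4HA3	11	73978243	G	A	0.32	6655	0.080	0.019	1.72e-5	2186	0.015	0.033	0.63	8841	0.064	0.016	7.27e-5
Vitamin-B12	CLYBL	13	100518634	C	T	0.035	6600	-0.203	0.047	1.83e-5	NA	NA	NA	NA	NA	NA	NA	NA
TNF-beta	HTRA4	8	38839282	GAA	G	0.013	6669	-0.292	0.069	2.68e-5	2188	0.378	0.141	0.73	8857	-0.172	0.062	5.54e-3
IL4	ATP10B	5	160113099	G	A	0.034	6673	0.186	0.045	3.55e-5	2189	0.141	0.086	0.10	8862	0.177	0.040	9.71e-6
FGF	P4HA3	11	73978243	G	A	0.32	6655	0.076	0.019	4.58e-5	2186	0.006	0.032	0.85	8841	0.059	0.016	2.81e-4
TNF-beta	ATP10B	5	160113099	G	A	0.034	6673	0.184	0.045	4.65e-5	2189	0.091	0.081	0.26	8862	0.164	0.039	3.26e-5
TNF-beta	ATP2C2	16	84495318	A	C	0.023	6660	0.223	0.055	4.69e-5	2188	-0.024	0.099	0.81	8848	0.170	0.048	3.86e-4
IFNG	ATP10B	5	160113099	G	A	0.034	6673	0.183	0.045	4.81e-5	2189	0.037	0.086	0.67	8862	0.152	0.040	1.45e-4
SDF1	ATP2C2	16	84495318	A	C	0.023	6660	0.221	0.055	5.69e-5	2188	0.057	0.105	0.59	8848	0.186	0.049	1.31e-4
TNF-beta	P4HA3	11	73978243	G	A	0.32	6655	0.075	0.019	5.94e-5	2186	0.007	0.031	0.81	8841	0.058	0.016	2.66e-4
FGF	ATP2C2	16	84495318	A	C	0.023	6660	0.220	0.055	5.98e-5	2188	0.033	0.105	0.75	8848	0.180	0.049	2.11e-4
IL18	EPPK1	8	144942134	CCTTT	C	0.023	6677	-0.232	0.058	6.20e-5	2160	-0.240	0.102	0.19	8837	-0.234	0.050	3.42e-6
PDGF	ATP10B	5	160113099	G	A	0.034	6673	0.181	0.045	6.20e-5	2189	-0.011	0.086	0.90	8862	0.139	0.040	4.84e-4
SDF1	ATP10B	5	160113099	G	A	0.034	6673	0.178	0.045	7.62e-5	2189	-0.118	0.085	0.17	8862	0.114	0.040	4.12e-3
Triglycerides	MS4A2	11	59863030	G	A	0.019	25051	0.129	0.033	7.80e-5	9489	0.151	0.054	4.85e-3	34540	0.135	0.028	1.31e-6
VEGF	HTRA4	8	38839282	GAA	G	0.013	6669	-0.274	0.069	7.86e-5	2188	-0.010	0.149	0.95	8857	-0.227	0.063	3.10e-4
IL17	CLYBL	13	100518634	C	T	0.035	6671	0.185	0.047	8.77e-5	NA	NA	NA	NA	NA	NA	NA	NA
IL10	ATP2C2	16	84495318	A	C	0.023	6660	0.214	0.055	9.33e-5	2188	0.134	0.105	0.20	8848	0.197	0.049	5.08e-5
IL6	P4HA3	11	73978243	G	A	0.32	6655	0.072	0.019	9.70e-5	2186	-0.016	0.033	0.62	8841	0.051	0.016	1.73e-3
IL17	HTRA4	8	38839282	GAA	G	0.013	6669	-0.270	0.069	1.03e-4	2188	-0.008	0.149	0.96	8857	-0.223	0.063	3.97e-4
IFN-gamma	CCL26	7	75401263	C	T	0.013	6663	-0.307	0.080	1.15e-4	2192	-0.183	0.133	0.17	8855	-0.274	0.068	5.94e-5
IL12	ATP10B	5	160113099	G	A	0.034	6673	0.174	0.045	1.20e-4	2189	0.010	0.086	0.91	8862	0.138	0.040	5.41e-4
IL6	ATP10B	5	160113099	G	A	0.034	6673	0.173	0.045	1.23e-4	2189	0.024	0.086	0.78	8862	0.141	0.040	4.15e-4
IL17	ATP10B	5	160113099	G	A	0.034	6673	0.173	0.045	1.24e-4	2189	-0.003	0.086	0.97	8862	0.135	0.040	7.13e-4
PDGF	P4HA3	11	73978243	G	A	0.32	6655	0.071	0.019	1.31e-4	2186	-0.022	0.032	0.50	8841	0.048	0.016	2.86e-3
GCSF	CLYBL	13	100518634	C	T	0.035	6671	0.180	0.047	1.41e-4	NA	NA	NA	NA	NA	NA	NA	NA
PDGF	ATP2C2	16	84495318	A	C	0.023	6660	0.209	0.055	1.43e-4	2188	0.048	0.105	0.65	8848	0.174	0.049	3.40e-4
GCSF	EFCAB3	17	60469326	C	T	0.043	6606	0.157	0.042	1.86e-4	2192	-0.157	0.079	0.046	8798	0.087	0.037	0.018
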