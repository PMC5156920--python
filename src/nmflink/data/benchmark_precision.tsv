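method	C.elegans	Email	Karate	Word	Jazz	USAir	Yeast	PB	NS	Router	Power	Baydry	School	SmaGri	SW
NMF1	0.142	0.111	0.201	0.042	0.548	0.320	0.139	0.143	0.265	0.025	0.022	0.477	0.195	0.053	0.123
NMF-D1	0.171	0.143	0.234	0.042	0.615	0.362	0.165	0.170	0.298	0.016	0.023	0.539	0.216	0.068	0.153
NMF-A1	0.175	0.143	0.214	0.042	0.605	0.386	0.168	0.170	0.311	0.021	0.026	0.541	0.218	0.068	0.153
NMF2	0.122	0.075	0.183	0.055	0.512	0.350	0.079	0.158	0.202	0.103	0.018	0.430	0.168	0.049	0.165
NMF-D2	0.185	0.144	0.201	0.079	0.593	0.445	0.169	0.234	0.303	0.067	0.029	0.520	0.182	0.118	0.246
NMF-A2	0.191	0.149	0.201	0.080	0.600	0.470	0.186	0.248	0.310	0.235	0.036	0.544	0.218	0.130	0.276
SPM	0.171	0.144	0.210	0.101	0.650	0.449	0.160	0.238	0.420	0.224	0.057	0.552	0.227	0.118	0.211
Katz	0.102	0.131	0.169	0.072	0.449	0.365	0.108	0.175	0.299	0.060	0.058	0.085	0.142	0.099	0.151
LHNII	0.000	0.000	0.000	0.001	0.047	0.003	0.000	0.000	0.008	0.000	0.010	0.005	0.062	0.000	0.001
ACT	0.053	0.024	0.128	0.087	0.169	0.332	0.000	0.077	0.193	0.160	0.034	0.118	0.142	0.035	0.101
TSCN	0.018	0.014	0.145	0.002	0.024	0.133	0.032	0.027	0.087	0.096	0.056	0.036	0.197	0.028	0.039
Salton	0.024	0.050	0.001	0.001	0.535	0.046	0.000	0.013	0.253	0.000	0.015	0.011	0.175	0.000	0.001
Jaccard	0.028	0.071	0.001	0.002	0.521	0.064	0.000	0.017	0.252	0.000	0.007	0.010	0.180	0.000	0.001
Sorenson	0.028	0.065	0.001	0.002	0.521	0.064	0.000	0.017	0.252	0.000	0.009	0.010	0.180	0.000	0.001
HPI	0.015	0.007	0.091	0.005	0.255	0.016	0.012	0.003	0.146	0.000	0.005	0.055	0.105	0.002	0.000
HDI	0.029	0.069	0.004	0.004	0.465	0.083	0.000	0.025	0.264	0.000	0.007	0.009	0.173	0.000	0.001
LHN	0.000	0.003	0.004	0.000	0.093	0.004	0.000	0.000	0.084	0.000	0.010	0.014	0.082	0.000	0.001
CN	0.095	0.139	0.164	0.064	0.509	0.372	0.104	0.174	0.379	0.057	0.051	0.065	0.162	0.090	0.112
AA	0.112	0.151	0.163	0.067	0.524	0.396	0.104	0.172	0.563	0.038	0.030	0.063	0.148	0.103	0.131
RA	0.112	0.138	0.165	0.056	0.545	0.473	0.083	0.151	0.586	0.020	0.030	0.065	0.187	0.102	0.139
PA	0.060	0.014	0.096	0.089	0.130	0.318	0.012	0.069	0.012	0.025	0.001	0.167	0.025	0.051	0.099
LP	0.100	0.131	0.169	0.072	0.495	0.370	0.107	0.175	0.299	0.059	0.054	0.071	0.113	0.095	0.128
CRA	0.116	0.157	0.199	0.038	0.557	0.391	0.123	0.177	0.481	0.062	0.033	0.085	0.210	0.118	0.147
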