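network	NN	NE	LD	AD	APL	C	CC	P	LCP-corr
C.elegans	297	2148	0.0489	14.4646	2.4553	0.0014	0.2924	-0.1632	0.9056
Email	1133	5451	0.0085	9.6222	3.6060	0.0002	0.1663	0.0782	0.8538
Karate	34	78	0.1390	4.5882	2.4082	0.0129	0.5706	-0.4756	0.7562
Word	112	425	0.0684	7.5893	2.5356	0.0036	0.1728	-0.1293	0.8528
Jazz	198	2742	0.1406	27.6970	2.2350	0.0023	0.6175	0.0202	0.9485
USAir	332	2126	0.0387	12.8072	2.7381	0.0011	0.6252	-0.2079	0.9799
Yeast	2361	6646	0.0024	5.6298	5.0960	0.0001	0.3057	0.4539	0.9686
PB	1222	16714	0.0224	27.3552	2.7375	0.0003	0.3203	-0.2213	0.9286
NS	379	914	0.0128	4.8232	6.0419	0.0004	0.7412	-0.0817	0.9224
Power	4941	6594	0.0005	2.6691	18.9892	0.0000	0.1032	0.0035	0.8456
Router	5022	6258	0.0005	2.4922	6.4488	0.0000	0.0303	-0.1384	0.8067
Baydry	128	2106	0.2591	32.9063	1.7724	0.0045	0.3346	-0.1044	0.9112
School	69	220	0.09378	6.3768	2.965	0.005	0.4606	0.0141	0.9005
SmaGri	1024	4916	0.0094	9.6016	2.9814	0.0003	0.3071	-0.1925	0.9463
SW	233	994	0.03678	8.5322	2.3711	0.0018	0.5564	-0.3027	0.9436
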