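# Synthetic stand-in amino-acid index table (24 indices x 20 amino acids).
# Indices SYN_01..SYN_20 are seeded pseudo-random values, not measured properties.
index	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
HYDROPATHY_KD	1.800	2.500	-3.500	-3.500	2.800	-0.400	-3.200	4.500	-3.900	3.800	1.900	-3.500	-1.600	-3.500	-4.500	-0.800	-0.700	4.200	-0.900	-1.300
MOLECULAR_WEIGHT	89.100	121.200	133.100	147.100	165.200	75.100	155.200	131.200	146.200	131.200	149.200	132.100	115.100	146.200	174.200	105.100	119.100	117.100	204.200	181.200
NET_CHARGE_PH7	0.000	0.000	-1.000	-1.000	0.000	0.000	0.100	0.000	1.000	0.000	0.000	0.000	0.000	0.000	1.000	0.000	0.000	0.000	0.000	0.000
RESIDUE_VOLUME	88.600	108.500	111.100	138.400	189.900	60.100	153.200	166.700	168.600	166.700	162.900	114.100	112.700	143.800	173.400	89.000	116.100	140.000	227.800	193.600
SYN_01	0.0922	0.7391	0.0348	-0.8307	0.3588	1.2474	0.5430	-0.3904	1.1137	-0.1554	-0.6114	0.1821	2.2270	-2.4583	0.3293	-0.5825	-0.7321	1.2413	2.6891	0.3255
SYN_02	-0.5963	-0.4246	0.6745	-0.8955	-0.9147	-0.0199	0.3993	0.2153	1.3053	0.6116	-1.1248	-1.6876	0.3411	0.6802	0.4986	0.5975	0.8256	0.1940	-0.2323	-0.0365
SYN_03	-1.0910	1.7024	0.7711	-2.9709	-1.9633	-0.9897	0.2304	0.6325	-0.5273	0.8652	-0.8180	-0.3080	-0.8303	-0.0387	-1.5429	-0.4869	-0.0451	0.9540	0.7986	0.1558
SYN_04	1.9144	-0.2196	-0.2521	0.0640	1.6322	0.2360	-0.5039	0.6052	1.0217	-0.0657	-0.1749	-0.0836	-0.0954	-0.6496	-0.5065	0.3474	0.5172	0.0890	0.0140	-0.0418
SYN_05	-1.3081	-0.4227	-0.6782	-0.8685	-0.5287	0.8395	-0.6830	-0.2006	0.1319	-0.7216	-0.3356	-0.8026	0.1006	0.7009	1.4103	0.6669	0.0167	-0.0397	-0.8992	-0.0340
SYN_06	0.7960	1.2860	0.2140	1.6250	-0.3477	-0.8836	0.4176	1.4008	-0.9170	0.1126	-0.3525	2.2861	0.8806	1.0170	2.5470	1.4005	-0.6004	0.3941	-0.4990	-0.5929
SYN_07	0.3805	0.8280	0.7937	-0.2888	-0.5162	-0.3507	-0.1312	1.1171	0.2890	0.7253	0.3905	0.1732	1.6344	1.2866	-0.8097	0.3298	0.4226	0.7013	0.3805	-0.2638
SYN_08	0.9715	-2.4651	1.0500	-0.6871	-0.1026	-1.6725	-0.5280	0.7093	0.1284	-0.4246	0.9461	0.0460	-0.7875	0.8312	-0.4569	-0.1571	0.0246	-0.8815	-1.5671	1.1914
SYN_09	-0.0785	-0.0873	-0.8342	0.9677	1.2139	-1.7647	-0.0980	-0.6824	0.6422	0.8990	0.0857	-1.2581	-0.8658	0.1024	-0.0901	-0.6490	-0.0560	-2.0036	2.0251	-1.2911
SYN_10	-0.1305	-0.4371	-1.1495	-0.3240	1.4405	-0.9309	-0.0850	-0.2435	-1.9413	2.8644	-0.9936	-0.0060	1.2722	0.2152	2.2547	-0.2184	-0.3267	0.8052	-0.5729	-0.7431
SYN_11	-0.3583	-1.1258	0.5777	-0.2691	0.9638	-0.1407	0.3645	1.1727	-0.6823	0.4292	1.5615	1.8463	0.1625	0.8471	-1.3272	-0.2264	1.2195	-0.4296	0.4807	2.2224
SYN_12	0.2214	0.3767	0.5150	0.3216	-0.1174	-0.1592	-0.2759	-0.3028	0.0316	0.5599	-0.1523	-0.9034	0.8573	-0.5929	0.9083	1.4113	-3.1503	-0.2804	0.1310	0.4648
SYN_13	-1.2673	-1.6349	-0.5875	0.0840	-2.2937	-1.5097	0.0342	-0.9635	0.5652	1.4436	-0.4846	-0.5551	-0.7301	0.9811	-1.9431	1.6156	-0.7212	-0.4271	1.2288	-0.5086
SYN_14	0.7851	-0.4464	-2.2090	0.2129	0.1003	1.1376	1.6786	-0.2827	-0.9278	-0.4898	1.9171	0.6664	1.2055	0.2861	0.5007	-0.7242	1.0042	0.1837	1.8333	0.6814
SYN_15	-1.0029	0.4458	0.0703	-1.8288	-0.1192	-1.8947	1.1124	0.9250	-1.0435	1.0666	0.3099	0.0639	3.0480	-0.3559	0.0102	1.5391	-0.3225	0.3856	-0.8161	-1.9343
SYN_16	2.0830	-0.1977	1.6470	0.7923	0.6361	-0.8360	1.1024	0.6418	1.1154	1.3068	0.6885	-0.3028	-0.3846	-0.9723	0.3785	-0.3316	0.7947	0.0415	0.0577	-1.0313
SYN_17	0.8266	0.5775	-0.6973	0.4285	-1.5323	-1.7271	0.8556	0.0286	0.1282	-0.3372	1.0232	0.5440	-0.8198	-0.7666	0.6668	-2.6636	-0.9159	1.9098	-1.0940	-0.0839
SYN_18	-0.3280	1.9013	-0.4886	-0.5115	0.9690	1.0059	1.5490	0.6153	0.9268	-0.1833	1.9497	0.8005	-0.3296	0.5139	1.8550	-0.2883	1.0342	-2.0390	0.2635	0.0793
SYN_19	2.5381	-2.1967	0.4609	0.6660	0.3461	2.4021	0.2949	0.7460	-2.0433	-1.6377	1.7775	1.3609	-0.9413	-2.2077	0.0926	0.7289	0.4334	-0.2703	0.3982	1.2843
SYN_20	0.2219	-0.6008	0.1042	-1.1349	-0.9416	-0.9889	-0.5478	-0.9136	1.3897	-0.3159	-0.1946	1.8194	0.3238	2.1674	0.9888	1.9188	0.4918	-0.3325	0.9502	0.2000
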