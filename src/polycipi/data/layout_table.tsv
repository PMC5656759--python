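name	accessions	host	seq_len	utr5_len	orf1_start	orf1_end	orf2b_start	orf2b_end	orf2_start	orf2_end	orf3_start	orf3_end	orf3a_start	orf3a_end	orf4_start	orf4_end	igr_len	orf5_start	orf5_end	utr3_len	extends_to_polya
SINV-2	EF428566.1;MF041813.1	Solenopsis invicta	11303	301	302	1078	1079	1309	1075	1878	1871	2647			2644	3792	662	4455	10916	387	yes
M. pharaonis TSA (LA858223)	LA858223.1	Monomorium pharaonis	11259	255	256	984	985	1221	981	1763	1753	2547			2544	3692	658	4351	10812	447	yes
LniV-1	MF041812.1	Lasius niger	11092	134	135	899	900	1157	896	1705	1695	2507			2507	3970	687	4658			no
L. neglectus TSA	LI526777.1	Lasius neglectus	11854	366	367	1131	1132	1392	1128	1940	1930	2742			2742	4181	657	4839	11375	479	yes
L. humile TSA	LI719284.1	Linepithema humile	11245	258	259	1011	1015	1305	1011	1817	1804	2664			2661	3872	385	4258	10860	385	yes
M. pharaonis TSA (LA866448)	LA866448.1	Monomorium pharaonis	12160	230	231	1064	1069	1434	1065	1898	1891	2697			2702	4018	759	4778	11719	441	yes
Shuangao insect virus 8	KX883910.1	Insects mix (1)	12155	224	225	1046	1050	1415	1046	1882	1875	2693			2690	4033	768	4802	11755	400	no
SINV-4	MF041808.1	Solenopsis invicta	12077	198	199	1065	1069	1434	1065	1898	1891	2697			2697	4034	734	4769	11662	415	yes
MsaV-1	MF041810.1	Myrmica scabrinodis	11872	228	229	1062	1111	1482	1059	1973	1970	2773			2776	4134	438	4573	11430	442	yes
LneV-1	MF041809.1	Lasius neglectus	11821	207	208	1053	1099	1422	1050	1946	1943	2782			2772	4259	336	4596	11402	419	yes
F. exsecta TSA	LH935078.1;LH935077.1	Formica exsecta	11899	206	207	1046	1080	1388	1043	1876	2079	2879	1873	2082	2882	4300	386	4687	11535	364	no
Hubei picorna-like virus 81 (KX884540)	KX884540.1	Procambarus clarkia	8116									84			81	1019	357	1377	8006	110	no
Hubei picorna-like virus 81 (KX883940)	KX883940.1	Insects mix (2)	10315	189	190	867			857	1540	1537	2157			2154	3098	353	3452	10078	237	no
Ch. riparius TSA	KA182589.1	Chironomus riparius	11462	365	366	1109			1109	1627	1630	2418			2421	3413	384	3798	11144	318	no
Hubei picorna-like virus 82	KX883688.1	Spiders mix	11081	279	280	1023			1023	1751	1748	2722			2719	3723	442	4166	10939	142	no
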