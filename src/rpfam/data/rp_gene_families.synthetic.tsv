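gene_id	family_id	subunit	is_pseudogene	cdna_length_bp
AT4G53123	RPL4	RPL	False	846
AT5G20853	RPL4	RPL	False	559
AT5G37773	RPL4	RPL	False	1316
AT5G25836	RPL4	RPL	True	1668
AT1G69215	RPL5	RPL	False	1318
AT3G02348	RPL5	RPL	False	681
AT3G27340	RPL5	RPL	False	2154
AT4G44012	RPL5	RPL	True	1715
AT3G59276	RPL6	RPL	False	2344
AT4G18934	RPL6	RPL	False	2166
AT1G79474	RPL7a	RPL	False	748
AT3G37186	RPL7a	RPL	False	1143
AT4G03760	RPL7a	RPL	False	2318
AT2G76420	RPL9	RPL	False	1113
AT3G56695	RPL9	RPL	False	1139
AT5G23738	RPL9	RPL	False	1747
AT2G32989	RPL10a	RPL	False	1490
AT3G72558	RPL10a	RPL	False	1412
AT3G74653	RPL10a	RPL	False	426
AT2G01921	RPL12	RPL	False	1103
AT4G35033	RPL12	RPL	False	1360
AT3G34274	RPL13	RPL	False	1920
AT3G48006	RPL13	RPL	False	451
AT5G05196	RPL13	RPL	False	485
AT2G53069	RPL15	RPL	False	2108
AT3G66896	RPL15	RPL	False	608
AT4G41596	RPL15	RPL	False	1198
AT1G23852	RPL18a	RPL	False	2245
AT2G50815	RPL18a	RPL	False	1357
AT3G13412	RPL18a	RPL	False	2368
AT5G44083	RPL18a	RPL	False	628
AT3G22580	RPL22	RPL	False	762
AT3G26116	RPL22	RPL	False	1262
AT4G60777	RPL22	RPL	True	1057
AT1G33285	RPL23	RPL	False	364
AT1G59970	RPL23	RPL	False	811
AT4G05305	RPL23	RPL	False	1347
AT2G26513	RPL23a	RPL	False	1068
AT2G45199	RPL23a	RPL	False	2107
AT3G17958	RPL23a	RPL	False	1954
AT4G71926	RPL23a	RPL	False	1684
AT1G38371	RPL26	RPL	False	1927
AT4G62765	RPL26	RPL	False	1523
AT5G22428	RPL26	RPL	False	1761
AT2G12579	RPL28	RPL	False	635
AT5G59136	RPL28	RPL	False	1569
AT1G62011	RPL29	RPL	False	968
AT2G40753	RPL29	RPL	False	887
AT3G06574	RPL29	RPL	False	1386
AT3G30831	RPL29	RPL	False	912
AT1G76826	RPL34	RPL	False	1683
AT5G69815	RPL34	RPL	False	1145
AT4G36057	RPL35a	RPL	False	534
AT5G45319	RPL35a	RPL	False	2267
AT2G59395	RPL36	RPL	False	1203
AT4G76440	RPL36	RPL	False	882
AT5G25469	RPL36a	RPL	False	389
AT5G31317	RPL36a	RPL	False	2393
AT5G50870	RPL36a	RPL	False	1014
AT2G38525	RPL36a	RPL	True	582
AT1G04207	RPL37	RPL	False	1276
AT2G43458	RPL37	RPL	False	1095
AT5G55263	RPL37	RPL	False	2193
AT5G73293	RPL37	RPL	True	1973
AT3G19052	RPL37a	RPL	False	686
AT4G74933	RPL37a	RPL	False	2178
AT5G32302	RPL37a	RPL	False	1594
AT3G39280	RPL38	RPL	False	326
AT3G79630	RPL38	RPL	False	1557
AT1G33796	RPL39	RPL	False	827
AT1G67616	RPL39	RPL	False	720
AT5G46479	RPL39	RPL	False	790
AT4G13194	RPL40	RPL	False	1116
AT5G13062	RPL40	RPL	False	1912
AT5G38219	RPL40	RPL	False	1887
AT2G65231	RPL40	RPL	True	510
AT3G46953	RPL41	RPL	False	2205
AT5G62792	RPL41	RPL	False	1463
AT1G33409	RPLP3	RPLP	False	923
AT2G61366	RPLP3	RPLP	False	1356
AT3G07083	RPLP3	RPLP	False	2064
AT1G10253	RPSa	RPS	False	673
AT2G37242	RPSa	RPS	False	2077
AT5G56372	RPSa	RPS	False	1795
AT2G18394	RPS3	RPS	False	782
AT2G70947	RPS3	RPS	False	2288
AT5G43199	RPS3	RPS	False	2085
AT5G40837	RPS3	RPS	True	527
AT3G44662	RPS3a	RPS	False	2341
AT3G78119	RPS3a	RPS	False	924
AT2G66576	RPS4	RPS	False	1071
AT2G72887	RPS4	RPS	False	1575
AT3G30461	RPS4	RPS	False	1975
AT3G66610	RPS4	RPS	False	1269
AT1G17405	RPS5	RPS	False	617
AT1G35238	RPS5	RPS	False	922
AT3G60424	RPS5	RPS	False	486
AT4G31004	RPS5	RPS	True	1875
AT1G57084	RPS6	RPS	False	2399
AT2G50360	RPS6	RPS	False	2309
AT2G77044	RPS6	RPS	False	1813
AT4G16790	RPS6	RPS	False	612
AT4G17702	RPS6	RPS	False	1720
AT2G55668	RPS7	RPS	False	517
AT4G29854	RPS7	RPS	False	1692
AT5G06073	RPS7	RPS	False	1933
AT1G62977	RPS10	RPS	False	1275
AT3G13067	RPS10	RPS	False	1538
AT4G42144	RPS10	RPS	False	1690
AT5G21994	RPS10	RPS	False	365
AT4G25921	RPS10	RPS	True	2209
AT2G17784	RPS11	RPS	False	1011
AT5G17586	RPS11	RPS	False	2115
AT1G15652	RPS12	RPS	False	1737
AT3G16904	RPS12	RPS	False	894
AT2G38495	RPS13	RPS	False	2144
AT2G55939	RPS13	RPS	False	373
AT5G08688	RPS13	RPS	False	564
AT5G47265	RPS13	RPS	False	1212
AT1G78434	RPS14	RPS	False	578
AT3G08759	RPS14	RPS	False	761
AT4G04842	RPS14	RPS	True	2176
AT2G29708	RPS17	RPS	False	1180
AT3G46780	RPS17	RPS	False	2296
AT3G76413	RPS17	RPS	False	837
AT1G48645	RPS18	RPS	False	790
AT4G57679	RPS18	RPS	False	1915
AT5G79833	RPS18	RPS	False	1322
AT1G44545	RPS20	RPS	False	1155
AT3G01367	RPS20	RPS	False	2075
AT1G24555	RPS21	RPS	False	1102
AT1G74306	RPS21	RPS	False	2151
AT5G13060	RPS21	RPS	False	1200
AT5G68270	RPS21	RPS	False	2346
AT5G78820	RPS21	RPS	False	748
AT2G06713	RPS24	RPS	False	712
AT2G62918	RPS24	RPS	False	1217
AT3G22847	RPS26	RPS	False	720
AT3G25449	RPS26	RPS	False	598
AT4G46095	RPS26	RPS	False	1656
AT5G72540	RPS26	RPS	False	1226
AT1G18454	RPS27	RPS	False	311
AT1G61926	RPS27	RPS	False	1467
AT3G00438	RPS27	RPS	False	924
AT2G66527	RPS28	RPS	False	945
AT2G70887	RPS28	RPS	False	1305
AT2G79297	RPS28	RPS	False	1655
AT5G24885	RPS28	RPS	False	1205
AT5G74350	RPS28	RPS	False	2122
AT1G28420	RPS29	RPS	False	2251
AT1G45775	RPS29	RPS	False	1387
AT3G24451	RPS29	RPS	False	972
AT3G20934	RPS30	RPS	False	946
AT5G36063	RPS30	RPS	False	1368
AT5G52689	RPS30	RPS	False	1223
AT1G20427	RPL3	RPL	False	561
AT4G64936	RPL3	RPL	False	444
AT2G76010	RPL7	RPL	False	1177
AT4G10678	RPL7	RPL	False	738
AT2G76570	RPL8	RPL	False	1191
AT5G38990	RPL8	RPL	False	2196
AT1G33108	RPL10	RPL	False	568
AT2G18875	RPL10	RPL	False	696
AT2G34305	RPL10	RPL	False	553
AT4G33480	RPL10	RPL	False	2033
AT5G28150	RPL10	RPL	False	2170
AT1G14138	RPL11	RPL	False	1220
AT1G40906	RPL11	RPL	False	389
AT2G69140	RPL11	RPL	False	1613
AT1G60392	RPL13a	RPL	False	1688
AT2G72601	RPL13a	RPL	False	815
AT5G01302	RPL13a	RPL	False	1167
AT5G74015	RPL13a	RPL	False	1941
AT2G07220	RPL13a	RPL	True	996
AT1G20746	RPL14	RPL	False	1841
AT3G11760	RPL14	RPL	False	407
AT4G53144	RPL14	RPL	False	2006
AT2G47622	RPL17	RPL	False	426
AT5G57739	RPL17	RPL	False	381
AT1G22573	RPL18	RPL	False	698
AT3G28956	RPL18	RPL	False	2343
AT5G68494	RPL18	RPL	False	2160
AT1G48325	RPL18	RPL	True	993
AT1G40372	RPL19	RPL	False	1010
AT2G47740	RPL19	RPL	False	2000
AT1G14054	RPL21	RPL	False	1193
AT2G14492	RPL21	RPL	False	1836
AT1G35949	RPL24	RPL	False	2135
AT2G13943	RPL24	RPL	False	310
AT5G06707	RPL24	RPL	False	799
AT5G41758	RPL24	RPL	False	1231
AT4G21677	RPL24	RPL	True	2147
AT1G06713	RPL27	RPL	False	1201
AT1G41420	RPL27	RPL	False	1525
AT2G63547	RPL27	RPL	False	1783
AT5G45699	RPL27	RPL	False	1263
AT2G63955	RPL27a	RPL	False	2314
AT3G37034	RPL27a	RPL	False	1753
AT4G52852	RPL27a	RPL	False	1922
AT4G55051	RPL27a	RPL	False	1244
AT1G76392	RPLP0	RPLP	False	308
AT3G09694	RPLP0	RPLP	False	1479
AT3G11641	RPLP0	RPLP	False	788
AT4G55020	RPLP1	RPLP	False	354
AT5G57107	RPLP1	RPLP	False	326
AT1G11221	RPLP2	RPLP	False	801
AT2G23015	RPLP2	RPLP	False	1735
AT4G56068	RPLP2	RPLP	False	2174
AT1G39075	RPL30	RPL	False	1544
AT1G60315	RPL30	RPL	False	380
AT1G53411	RPL31	RPL	False	2030
AT4G22254	RPL31	RPL	False	1799
AT4G41287	RPL31	RPL	False	719
AT5G70034	RPL31	RPL	False	2228
AT2G43539	RPL32	RPL	False	407
AT2G52846	RPL32	RPL	False	397
AT5G08104	RPL32	RPL	False	1331
AT1G27822	RPL35	RPL	False	846
AT2G08003	RPL35	RPL	False	2290
AT2G17899	RPL35	RPL	False	2269
AT3G26775	RPS2	RPS	False	723
AT4G36082	RPS2	RPS	False	988
AT3G66719	RPS2	RPS	True	1882
AT1G26531	RPS8	RPS	False	709
AT2G28100	RPS8	RPS	False	1308
AT4G78282	RPS8	RPS	False	1672
AT3G50088	RPS8	RPS	True	1040
AT5G28902	RPS9	RPS	False	1811
AT5G37368	RPS9	RPS	False	1650
AT5G62024	RPS9	RPS	True	2018
AT1G35283	RPS15	RPS	False	2025
AT2G03439	RPS15	RPS	False	2340
AT2G09762	RPS15	RPS	False	2297
AT3G37073	RPS15	RPS	False	1813
AT4G60165	RPS15	RPS	False	1164
AT5G21495	RPS15	RPS	False	1771
AT1G48046	RPS15a	RPS	False	424
AT2G07263	RPS15a	RPS	False	2112
AT3G28827	RPS15a	RPS	False	1473
AT1G01112	RPS16	RPS	False	1701
AT1G12836	RPS16	RPS	False	960
AT2G52451	RPS16	RPS	False	2256
AT1G25482	RPS19	RPS	False	1811
AT4G43526	RPS19	RPS	False	1578
AT1G58643	RPS23	RPS	False	1909
AT3G58014	RPS23	RPS	False	716
AT1G03947	RPS25	RPS	False	2142
AT1G31924	RPS25	RPS	False	2312
AT5G41684	RPS25	RPS	False	1082
AT1G54389	RPS27a	RPS	False	2204
AT2G79282	RPS27a	RPS	False	1670
AT3G19705	RPS27a	RPS	False	1871
AT4G05740	RPS27a	RPS	False	1094
AT1G24125	RPL2	RPL	False	1898
AT3G63147	RPL2	RPL	False	537
AT4G68721	RPL2	RPL	False	1147
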