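sample	uracil_qams	uracil_esm	uridine_qams	uridine_esm	adenine_qams	adenine_esm	guanosine_qams	guanosine_esm	adenosine_esm
1	0.1393	0.1341	2.504	2.398	0.3191	0.3016	2.593	2.404	2.670
2	0.2357	0.2269	2.540	2.432	0.3891	0.3677	2.565	2.379	2.784
3	0.2220	0.2138	2.810	2.694	0.3530	0.3336	2.695	2.466	2.851
4	0.2235	0.2151	2.368	2.267	0.2805	0.2652	2.287	2.121	2.476
5	0.1123	0.1081	1.899	1.189	0.2468	0.2332	1.950	1.808	2.275
6	0.1275	0.1228	2.535	2.427	0.2694	0.2417	2.653	2.460	2.982
7	0.1326	0.1276	2.517	2.409	0.2913	0.2753	2.464	2.284	2.740
8	0.1100	0.1058	2.582	2.518	0.2439	0.2305	2.620	2.430	3.009
9	0.1404	0.1351	1.997	1.192	0.2219	0.2097	2.180	2.021	2.518
10	0.2235	0.2151	3.024	2.896	0.3798	0.3590	2.574	2.387	2.714
11	0.1599	0.1539	1.573	1.506	0.2369	0.2264	1.547	1.434	1.583
12	0.1646	0.1585	1.624	1.555	0.2479	0.2343	1.591	1.475	1.629
13	0.0999	0.0961	1.775	1.670	0.1984	0.1875	1.650	1.530	1.745
14	0.1617	0.1557	1.593	1.525	0.2394	0.2262	1.558	1.444	1.595
15	0.1149	0.1106	2.039	1.925	0.2301	0.2174	1.861	1.726	1.957
16	0.1278	0.1231	1.718	1.645	0.2090	0.1975	1.674	1.552	1.752
17	0.1101	0.1065	2.335	2.236	0.2277	0.2152	1.698	1.575	1.858
18	0.1099	0.1058	2.295	2.197	0.2091	0.1977	1.665	1.544	1.828
19	0.1143	0.1100	2.385	2.284	0.2406	0.2273	1.737	1.611	1.896
20	0.1077	0.1031	1.850	1.772	0.2059	0.1946	1.762	1.634	1.830
21	0.1098	0.1057	1.158	1.109	0.0785	0.0742	2.241	2.078	2.269
22	0.1068	0.1028	1.283	1.229	0.0834	0.0789	2.325	2.156	2.207
23	0.1023	0.0985	1.067	1.022	0.0756	0.0714	1.946	1.804	1.684
24	0.0914	0.0879	0.737	0.707	0.0597	0.0564	1.524	1.413	1.370
25	0.0897	0.0864	0.974	0.932	0.0925	0.0875	2.111	1.958	1.901
26	0.1028	0.0989	1.249	1.197	0.0636	0.0599	2.251	2.088	2.257
27	0.1569	0.1510	1.697	1.625	0.1281	0.1208	3.048	2.827	2.755
28	0.1401	0.1348	1.532	1.467	0.1211	0.1145	2.689	2.493	2.538
29	0.0851	0.0819	0.969	0.928	0.0741	0.0701	1.893	1.756	1.816
30	0.1007	0.0969	1.245	1.192	0.0711	0.0672	2.526	2.343	2.595
correlation	0.9999	0.9998	0.9997	0.9999	
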