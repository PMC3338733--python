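site_id	site	mean	std	normalized	normalized_std
24	Lymph Nodes (reg)	5.6414	0.4919	1.0000	0.0872
25	Lymph Nodes (dist)	8.3541	0.8096	1.4809	0.1435
1	Adrenal	10.0349	1.0068	1.7788	0.1785
22	Liver	10.6139	1.0226	1.8814	0.1813
23	Lung	13.0284	1.1497	2.3094	0.2038
6	Bone	16.0277	1.4508	2.8411	0.2572
18	Kidney	20.3944	1.9664	3.6151	0.3486
33	Pleura	22.9329	2.4375	4.0651	0.4321
28	Pancreas	26.4350	2.6438	4.6859	0.4686
41	Spleen	33.7009	3.4925	5.9739	0.6191
17	Heart	36.5513	3.6359	6.4791	0.6445
7	Brain	40.5540	4.3179	7.1886	0.7654
44	Thyroid	41.3240	4.0700	7.3251	0.7215
30	Pericardium	46.8599	4.1645	8.3064	0.7382
12	Diaphragm	51.3372	5.6196	9.1001	0.9961
31	Peritoneum	51.9555	5.4518	9.2097	0.9664
19	Large Intestine	69.0501	7.3192	12.2399	1.2963
39	Skin	79.2006	8.4505	14.0392	1.4979
16	Gallbladder	104.9654	10.0373	18.6063	1.7792
40	Small Intestine	105.8723	9.9567	18.7670	1.7649
42	Stomach	122.4070	12.7034	21.6980	2.2518
26	Omentum	155.6364	15.8049	27.5883	2.8016
38	Skeletal Muscle	313.7172	30.6400	55.6098	5.4313
5	Bladder	620.7585	63.7243	110.0362	11.2958
34	Prostate	630.6260	68.4618	111.7854	12.1356
49	Vagina	630.8929	64.6222	111.8327	11.4550
48	Uterus	633.1578	63.9966	112.2342	11.3441
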