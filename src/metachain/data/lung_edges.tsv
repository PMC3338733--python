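rank	site_id	site	one_step_mean	one_step_std	two_step_prob	two_step_intermediate_id
1	24	Lymph Nodes (reg)	0.15115	0.01821	0.02819	24
2	1	Adrenal	0.13165	0.01953	0.01397	24
3	25	Lymph Nodes (dist)	0.11928	0.00279	0.01860	24
4	22	Liver	0.08028	0.00946	0.01440	24
5	18	Kidney	0.06677	0.01231	0.00709	24
6	6	Bone	0.05914	0.00196	0.00931	24
7	23	Lung	0.05223	0.01504	0.01214	24
8	33	Pleura	0.04735	0.00338	0.00657	24
9	28	Pancreas	0.04660	0.00785	0.00549	24
10	17	Heart	0.03639	0.00739	0.00407	24
11	41	Spleen	0.03415	0.00454	0.00432	24
12	7	Brain	0.03274	0.00728	0.00360	24
13	44	Thyroid	0.03180	0.00628	0.00356	24
14	30	Pericardium	0.02733	0.00557	0.00306	24
15	12	Diaphragm	0.02169	0.00216	0.00289	24
16	19	Large Intestine	0.01724	0.00266	0.00219	24
17	16	Gallbladder	0.01015	0.00048	0.00145	24
18	42	Stomach	0.00949	0.00139	0.00119	24
19	40	Small Intestine	0.00786	0.00158	0.00149	24
20	38	Skeletal Muscle	0.00413	0.00093	0.00047	24
21	39	Skin	0.00439	0.00443	0.00203	24
22	31	Peritoneum	0.00384	0.00567	0.00308	24
23	26	Omentum	0.00305	0.00223	0.00103	24
24	34	Prostate	0.00064	0.00060	0.00025	24
25	49	Vagina	0.00052	0.00059	0.00025	24
26	5	Bladder	0.00009	0.00029	0.00023	1
27	48	Uterus	0.00007	0.00025	0.00022	1
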