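site_id	name	in_lung_target
1	Adrenal	true
2	Anus	false
3	Appendix	false
4	Bile Duct	false
5	Bladder	false
6	Bone	true
7	Brain	true
8	Branchial Cyst	false
9	Breast	false
10	Cervix	false
11	Colon	false
12	Diaphragm	true
13	Duodenum	false
14	Esophagus	false
15	Eye	false
16	Gallbladder	true
17	Heart	true
18	Kidney	true
19	Large Intestine	true
20	Larynx	false
21	Lip	true
22	Liver	true
23	Lung	true
24	Lymph Nodes (reg)	true
25	Lymph Nodes (dist)	true
26	Omentum	true
27	Ovaries	false
28	Pancreas	true
29	Penis	false
30	Pericardium	true
31	Peritoneum	true
32	Pharynx	false
33	Pleura	true
34	Prostate	true
35	Rectum	false
36	Retroperitoneum	false
37	Salivary	false
38	Skeletal Muscle	true
39	Skin	true
40	Small Intestine	true
41	Spleen	true
42	Stomach	true
43	Testes	false
44	Thyroid	true
45	Tongue	false
46	Tonsil	false
47	Unknown	false
48	Uterus	true
49	Vagina	true
50	Vulva	false
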