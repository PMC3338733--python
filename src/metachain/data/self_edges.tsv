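site_id	site	mean	std
24	Lymph Nodes (reg)	0.1865	0.0152
25	Lymph Nodes (dist)	0.1231	0.0028
22	Liver	0.0945	0.0094
1	Adrenal	0.0929	0.0212
6	Bone	0.0616	0.0019
23	Lung	0.0522	0.0150
18	Kidney	0.0470	0.0143
33	Pleura	0.0434	0.0049
28	Pancreas	0.0360	0.0097
41	Spleen	0.0286	0.0057
17	Heart	0.0262	0.0088
44	Thyroid	0.0233	0.0076
7	Brain	0.0230	0.0092
31	Peritoneum	0.0211	0.0122
30	Pericardium	0.0203	0.0071
12	Diaphragm	0.0192	0.0031
19	Large Intestine	0.0141	0.0033
39	Skin	0.0140	0.0071
40	Small Intestine	0.0098	0.0019
16	Gallbladder	0.0097	0.0007
42	Stomach	0.0081	0.0019
26	Omentum	0.0068	0.0030
38	Skeletal Muscle	0.0032	0.0013
5	Bladder	0.0020	0.0025
48	Uterus	0.0020	0.0025
49	Vagina	0.0017	0.0012
34	Prostate	0.0017	0.0009
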