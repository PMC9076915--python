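sample_id	patient_id	subtype	timepoint	nri	pcr	rfs_time	rfs_event	purity	purity_rna	histology	regimen	recurrence	recurrence_location	vital_status
s97_pre	s97	ERpos	pre	0.33	no	NA	NA	0.70	0.70	IDC	6x ddAC	0	NA	A
s97_post	s97	ERpos	post	0.33	no	NA	NA	0.80	0.75	IDC	6x ddAC	0	NA	A
s188_pre	s188	TN	pre	0	no	NA	NA	0.80	NA	IDC	1x AC, 1x CD	1	Lung, brain	D
s188_post	s188	TN	post	0	no	NA	NA	0.80	NA	IDC	1x AC, 1x CD	1	Lung, brain	D
s2046_pre	s2046	TN	pre	0	no	NA	NA	0.70	0.50	IDC	6x ddAC	1	Liver	D
s2046_post	s2046	TN	post	0	no	NA	NA	0.70	0.70	IDC	6x ddAC	1	Liver	D
s2271_pre	s2271	TN	pre	0.33	no	NA	NA	0.80	0.90	IDC	6x ddAC	1	Thorax, lymph, contralateral mamma, skin	D
s2271_post	s2271	TN	post	0.33	no	NA	NA	0.55	0.55	IDC	6x ddAC	1	Thorax, lymph, contralateral mamma, skin	D
s2472_pre	s2472	TN	pre	0.33	no	NA	NA	NA	0.80	IDC	4x ddAC, 2x CTC+PSCT	1	Multiple lymph nodes, lung, liver	D
s2472_post	s2472	TN	post	0.33	no	NA	NA	NA	0.70	IDC	4x ddAC, 2x CTC+PSCT	1	Multiple lymph nodes, lung, liver	D
s2492_pre	s2492	TN	pre	0.333	no	NA	NA	0.90	0.60	IDC	6x ddAC	1	Brain	D
s2492_post	s2492	TN	post	0.333	no	NA	NA	0.50	0.50	IDC	6x ddAC	1	Brain	D
s2653_pre	s2653	ERpos	pre	0	no	NA	NA	NA	0.60	IDC	3x ddAC, 2x CD, 2x D	1	Bone	A
s2653_post	s2653	ERpos	post	0	no	NA	NA	NA	0.50	IDC	3x ddAC, 2x CD, 2x D	1	Bone	A
s2661_pre	s2661	ERpos	pre	0.2	no	NA	NA	0.90	0.90	Papillary carcinoma	6x ddAC	0	NA	A
s2661_post	s2661	ERpos	post	0.2	no	NA	NA	0.80	0.80	Papillary carcinoma	6x ddAC	0	NA	A
s2677_pre	s2677	ERpos	pre	0	no	NA	NA	0.50	0.50	ILC	6x ddAC	0	NA	A
s2677_post	s2677	ERpos	post	0	no	NA	NA	0.70	0.70	ILC	6x ddAC	0	NA	A
s2691_pre	s2691	ERpos	pre	0.333	no	NA	NA	0.40	0.40	IDC	6x ddAC	0	NA	A
s2691_post	s2691	ERpos	post	0.333	no	NA	NA	0.60	0.60	IDC	6x ddAC	0	NA	A
s2739_pre	s2739	ERpos	pre	0.33	no	NA	NA	0.80	0.80	IDC	3x AC, 3x CD	0	NA	A
s2739_post	s2739	ERpos	post	0.33	no	NA	NA	0.60	0.60	IDC	3x AC, 3x CD	0	NA	A
s2789_pre	s2789	ERpos	pre	0.33	no	NA	NA	0.60	0.60	IDC	6x ddAC	0	NA	A
s2789_post	s2789	ERpos	post	0.33	no	NA	NA	0.40	0.40	IDC	6x ddAC	0	NA	A
s2817_pre	s2817	ERpos	pre	0	no	NA	NA	0.70	0.70	IDC	3x AC, 3x CD	0	NA	A
s2817_post	s2817	ERpos	post	0	no	NA	NA	0.80	0.80	IDC	3x AC, 3x CD	0	NA	A
s2852_pre	s2852	ERpos	pre	0	no	NA	NA	0.70	0.70	IDC	3x ddAC	1	Bone, liver	A
s2852_post	s2852	ERpos	post	0	no	NA	NA	0.60	0.60	IDC	3x ddAC	1	Bone, liver	A
s2976_pre	s2976	ERpos	pre	0	no	NA	NA	0.70	0.70	IDC	3x ddAC, 4x paclitaxel	0	NA	A
s2976_post	s2976	ERpos	post	0	no	NA	NA	0.50	0.50	IDC	3x ddAC, 4x paclitaxel	0	NA	A
s3001_pre	s3001	ERpos	pre	0	no	NA	NA	0.60	0.60	IDC	6x ddAC	0	NA	A
s3001_post	s3001	ERpos	post	0	no	NA	NA	0.65	0.65	IDC	6x ddAC	0	NA	A
s3036_pre	s3036	ERpos	pre	0.25	no	NA	NA	0.50	0.50	IDC	6x ddAC	0	NA	A
s3036_post	s3036	ERpos	post	0.25	no	NA	NA	0.50	0.50	IDC	6x ddAC	0	NA	A
s3065_pre	s3065	ERpos	pre	0	no	NA	NA	0.70	0.70	IDC	6x ddAC	0	NA	A
s3065_post	s3065	ERpos	post	0	no	NA	NA	0.60	0.60	IDC	6x ddAC	0	NA	A
s3067_pre	s3067	ERpos	pre	0	no	NA	NA	0.60	0.60	ILC	6x ddAC	0	NA	A
s3067_post	s3067	ERpos	post	0	no	NA	NA	0.60	0.60	ILC	6x ddAC	0	NA	A
s3130_pre	s3130	ERpos	pre	0	no	NA	NA	0.60	0.60	IDC	6x ddAC	0	NA	A
s3130_post	s3130	ERpos	post	0	no	NA	NA	0.55	0.55	IDC	6x ddAC	0	NA	A
s3161_pre	s3161	ERpos	pre	0	no	NA	NA	0.60	0.60	IDC	3x ddAC, 9x paclitaxel	0	NA	A
s3161_post	s3161	ERpos	post	0	no	NA	NA	0.80	0.80	IDC	3x ddAC, 9x paclitaxel	0	NA	A
s3280_pre	s3280	TN	pre	NA	no	NA	NA	0.60	NA	Metaplastic	3x ddAC, 3x carbo/paclitaxel	0	NA	A
s3280_post	s3280	TN	post	NA	no	NA	NA	0.60	NA	Metaplastic	3x ddAC, 3x carbo/paclitaxel	0	NA	A
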