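label	p0_injected	f1_fluorescent	f2_phenotype_positive	f1_pcr_positive	f2_pcr_positive	cas9_targets	targeting_vector	distance_cM	background
tmIn42-44	146	900	163	4	3	egl-4 unc-17	no	11.5	WT
tmIn45	149	723	87	10	1	egl-4 unc-17	no	11.5	lig-4
wt_vector	107	755	102	12	0	egl-4 unc-17	yes	11.5	WT
tmIn1	31	136	40	6	1	egl-4 unc-17	yes	11.5	lig-4
tmIn2	48	168	24	2	1	ced-2 unc-17	yes	13.5	lig-4
tmIn3	46	312	96	25	1	jtr-1 unc-17	yes	16.4	lig-4
csn4_egl4	39	168	64	4	0	csn-4 egl-4	yes	7.6	lig-4
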