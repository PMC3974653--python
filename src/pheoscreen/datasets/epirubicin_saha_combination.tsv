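ic50_fold	dose_epi_nm	dose_saha_nm	fraction_affected	ci	effect	dri_epi	dri_saha
4	20	4000	0.808566317	0.719	Synergistic	8.227	1.674
2	10	2000	0.740589432	0.537	Synergistic	8.593	2.378
1	5	1000	0.588437471	0.568	Synergistic	5.459	2.6
0.5	2.5	500	0.446667935	0.553	Synergistic	4.23	3.156
0.25	1.25	250	0.328056979	0.518	Synergistic	3.675	4.069
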