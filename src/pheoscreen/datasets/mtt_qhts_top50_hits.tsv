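name	curve_class	ic50_um	efficacy_pct
Colchicine (Colcrys)	-1.1	0.47	-85
Dipyrithione (Crimanex)	-1.1	1.50	-81
Zinc pyrithione	-1.1	2.11	-91
1-Hydroxypyridine-2-thione zinc salt	-1.1	2.11	-96
Mersalyl sodium	-1.1	2.66	-92
Auranofin (Ridaura)	-1.1	2.66	-87
Thimerosal	-1.1	2.99	-87
Deslorelin acetate (Suprelorin)	-1.1	2.99	-89
Paclitaxel (Abraxane, Onxol)	-1.2	0.04	-51
5-Aza-2'-deoxycytidine, Decitabine (Dacogen)	-1.2	0.07	-52
Homoharringtonine	-1.2	0.24	-74
Trimetrexate glucuronate (Neutrexin)	-1.2	0.38	-51
Rubitecan (Orathecin)	-1.2	0.42	-55
Nocodazole	-1.2	0.53	-60
Fenbendazole (Panacur)	-1.2	1.01	-61
Artemisinimum	-1.2	1.33	-60
Carmofur (Mifurol)	-1.2	1.88	-57
Suberoylanilide hydroxamic acid (SAHA) (Zolinza)	-1.2	2.37	-59
Tenovin-1	-1.2	2.66	-56
Carubicinum	-1.2	2.99	-59
Captan	-1.2	2.99	-66
Lissamine green B	-1.2	6.68	-54
Mycophenolic acid (CellCept, Myfortic)	-2.1	1.14	-97
Tyrothricin	-2.1	1.50	-84
Mycophenolate mofetil	-2.1	1.68	-92
Brilliant Green	-2.1	1.68	-108
Rotenone	-2.1	2.66	-124
Lestaurtinib	-2.1	2.66	-83
Ciclopirox ethanolamine	-2.1	4.53	-85
RTA 402	-2.1	6.68	-108
Sanguinarine	-2.1	8.41	-88
Proflavine hemisulfate	-2.1	8.41	-92
Parthenolide	-2.1	8.41	-104
Bortezomib (Velcade)	-2.2	0.60	-75
Albendazole (Albenza)	-2.2	0.72	-58
Sobuzoxane (Perazolin)	-2.2	0.84	-56
Azacitidine (Vidaza)	-2.2	1.33	-71
Tiquizium bromide	-2.2	1.88	-52
Flavopiridol hydrochloride hydrate	-2.2	1.88	-71
Ancitabina	-2.2	2.37	-68
Ethaverine hydrochloride	-2.2	3.60	-60
2,2',4'-Trichloroacetophenone	-2.2	3.76	-71
Berberine chloride	-2.2	4.22	-54
17-Allylamino-geldanamycin (17-AAG)	-2.2	4.22	-81
Proguanil hydrochloride	-2.2	4.53	-60
Topotecan hydrochloride (Hycamtin)	-2.2	4.73	-90
Phenelzine sulfate	-2.2	5.08	-53
Oxapium iodide	-2.2	6.68	-60
Methyl violet	-2.2	7.50	-70
Malachite Green Oxalate	-2.2	8.41	-61
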