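strain	I	II	III	IV	V	VI	VII	UNCLASSIFIED
Prochlorococcus_marinus_MIT9303	2	0	0	1	1	0	0	0
Prochlorococcus_marinus_MIT9312	1	0	0	0	0	0	0	0
Prochlorococcus_marinus_MIT9313	2	0	0	1	2	0	0	0
Prochlorococcus_marinus_NATL1A	1	0	0	0	0	0	0	0
Prochlorococcus_marinus_NATL2A	1	0	0	0	0	0	0	0
Prochlorococcus_marinus_AS9601	1	0	0	0	0	0	0	0
Cyanobium_PCC7001	1	0	2	0	0	0	0	1
Synechococcus_PCC7335	1	0	0	0	1	0	0	0
Synechococcus_RS9916	1	0	0	1	1	0	0	0
Synechococcus_BL107	1	0	0	0	0	0	0	1
Synechococcus_WH7805	2	0	0	0	0	0	0	1
Synechococcus_WH5701	2	0	0	0	0	0	0	0
Synechococcus_RS9917	1	0	0	0	0	0	0	0
Synechococcus_WH8102	3	0	0	0	0	0	0	1
Synechococcus_RCC307	1	0	0	0	0	0	0	0
Synechococcus_CC9902	2	0	0	0	0	0	0	0
Synechococcus_elongatus_PCC6301	1	0	1	0	0	0	0	0
Synechococcus_elongatus_PCC7942	1	0	1	0	0	0	0	0
Synechococcus_PCC7002	1	0	0	0	0	0	0	0
Synechococcus_WH7803	2	0	0	0	1	0	0	0
Synechococcus_CC9311	1	0	0	0	0	0	0	1
Synechococcus_CC9605	1	0	0	0	1	0	0	0
Synechococcus_WH8109	1	0	0	0	0	0	0	0
Cyanothece_PCC7425	0	0	0	4	0	0	1	0
Cyanothece_PCC8802	1	2	0	1	0	0	0	0
Cyanothece_PCC7424	1	2	0	0	0	0	0	0
Cyanothece_PCC8801	1	2	0	1	0	0	0	0
Cyanothece_ATCC51142	3	1	0	0	0	0	0	0
Cyanothece_PCC7822	1	0	0	0	0	0	0	0
Cyanothece_CCY0110	1	2	0	0	0	0	0	0
Microcystis_aeruginosa_NIES843	1	1	0	0	0	0	0	0
Synechocystis_PCC6803	1	0	0	0	0	0	0	1
Arthrospira_maxima_CS328	1	0	0	0	0	0	0	0
Microcoleus_chthonoplastes_PCC7420	1	2	0	1	0	0	0	1
Trichodesmium_erythraeum_IMS101	1	1	1	0	0	0	1	0
Acaryochloris_marina_MBIC11017	3	0	1	0	0	0	0	0
Nostoc_punctiforme_PCC73102	2	2	1	4	3	1	1	0
Nostoc_sp_7120	3	1	3	1	1	1	0	1
Nostoc_azollae_0708	1	1	1	0	0	1	0	0
Anabaena_variabilis_ATCC29413	1	1	2	1	1	1	0	1
Nodularia_spumigena_CCY9414	1	3	2	0	0	1	0	0
Cylindrospermopsis_raciborskii_CS505	1	1	2	0	0	1	0	0
Raphidiopsis_brookii_D9	1	1	2	0	0	0	0	0
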