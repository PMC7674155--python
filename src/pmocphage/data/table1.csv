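site,year,name,short_name,length_bp,gc_percent,n_orfs,n_trnas,completeness,pmoc_taxonomy,related_pair,fragmented_pmoc,within_population_partial,partial_pmoc
"BML (Canada)",2015-2017,BML_pmoC-phage_2,BML_2,218687,33,342,15,Partial,Gamma-,False,False,False,False
"BML (Canada)",2015-2017,BML_pmoC-phage_3,BML_3,190971,34,272,20,Partial,Gamma-,True,True,True,False
"BML (Canada)",2015-2017,BML_pmoC-phage_4,BML_4,243619,34,342,18,Complete,Gamma-,False,True,False,False
"BML_S (Canada)",2017,BML_S_phage_1,BML_S_1,167437,40,212,24,Complete,,False,False,False,False
"TP6 (Canada)",2012,TP6_pmoC-phage_1,TP6_1,308538,37,406,29,Partial,Gamma-,False,True,False,False
"PDSYNTPWS (Canada)",2012,PDSYNTPWS_phage_1,PDSYNTPWS_1,222435,34,358,20,Partial,,True,False,False,False
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_pmoC-phage_1,LM_1,174291,41,249,21,Complete,Alpha-,False,False,False,False
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_pmoC-phage_2,LM_2,174276,39,263,24,Complete,Alpha-,False,False,False,False
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_pmoC-phage_3,LM_3,172382,41,249,21,Complete,Alpha-,False,False,False,False
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_pmoC-phage_4,LM_4,353177,32,465,14,Complete,Gamma-,False,False,False,False
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_pmoC-phage_5,LM_5,166198,38,245,19,Complete,Alpha-,False,False,False,False
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_pmoC-phage_6,LM_6,198907,34,313,20,Partial,Gamma-,True,False,False,False
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_phage_7,LM_7,166826,39,238,25,Complete,,False,False,False,False
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_pmoC-phage_8,LM_8,167952,39,252,25,Complete,Alpha-,False,False,False,True
"Lake Mendota (Madison, WI, United States)",2008-2012,Lake_Mendota_phage_9,LM_9,172107,40,240,22,Complete,,False,False,False,False
"Crystal Bog (Madison, WI, United States)",2007-2009,Crystal_Bog_pmoC-phage_1,CB_1,352383,35,445,23,Complete,Alpha-,False,False,False,False
"Crystal Bog (Madison, WI, United States)",2007-2009,Crystal_Bog_pmoC-phage_2,CB_2,527138,38,594,13,Complete,Alpha-,False,False,False,False
"Crystal Bog (Madison, WI, United States)",2007-2009,Crystal_Bog_pmoC-phage_3,CB_3,166456,35,247,18,Complete,Gamma-,False,False,False,False
"Crystal Bog (Madison, WI, United States)",2007-2009,Crystal_Bog_pmoC-phage_4,CB_4,165508,38,264,4,Complete,Alpha-,False,False,False,False
"Crystal Bog (Madison, WI, United States)",2007-2009,Crystal_Bog_pmoC-phage_5,CB_5,166149,44,248,4,Complete,Alpha-,False,False,True,False
"Crystal Bog (Madison, WI, United States)",2007-2009,Crystal_Bog_phage_6,CB_6,174375,38,233,0,Complete,,False,False,False,False
"Lake Rotsee (Switzerland)",2017-2018,Lake_Rotsee_pmoC-phage_1,LR_1,168581,40,224,4,Complete,Alpha-,False,False,False,False
"Lake Rotsee (Switzerland)",2017-2018,Lake_Rotsee_pmoC-phage_2,LR_2,160734,37,241,6,Complete,Alpha-,False,False,False,False
"Lake Rotsee (Switzerland)",2017-2018,Lake_Rotsee_pmoC-phage_3,LR_3,159173,35,248,10,Complete,Gamma-,False,False,False,False
"Lake Rotsee (Switzerland)",2017-2018,Lake_Rotsee_pmoC-phage_4,LR_4,365676,36,467,4,Complete,Gamma-,False,False,False,False
"Lake Rotsee (Switzerland)",2017-2018,Lake_Rotsee_pmoC-phage_5,LR_5,341475,36,463,15,Complete,Gamma-,False,False,False,False
"Lake Rotsee (Switzerland)",2017-2018,Lake_Rotsee_pmoC-phage_6,LR_6,314403,38,442,0,Complete,Gamma-,False,True,False,False
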