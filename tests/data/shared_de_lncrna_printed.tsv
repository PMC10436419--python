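feature_id	log2fc_SFvsSC	pvalue_SFvsSC	log2fc_HFvsHC	pvalue_HFvsHC
MSTRG.6499.1	-1.62164	0.001348	2.462827	0.025799
MSTRG.13184.1	-1.13768	0.031056	2.304492	0.025538
MSTRG.15334.1	-1.30368	0.020797	3.109891	4.68E-15
MSTRG.7445.4	-2.20322	0.004863	-1.71373	0.040012
MSTRG.7446.1	-1.64523	0.00593	-1.91793	0.000547
MSTRG.32396.1	-4.76054	0.000157	-4.31963	0.000309
MSTRG.7445.5	-1.66949	0.014645	-2.26355	0.018517
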