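feature_id	log2fc_SFvsSC	pvalue_SFvsSC	log2fc_HFvsHC	pvalue_HFvsHC
ENSBTAG00000020676	1.02141	0.015537	1.159553	0.044376
ENSBTAG00000033278	1.015077	0.016469	-1.2502	0.013512
ENSBTAG00000046900	1.288896	0.002164	-1.20589	0.028207
ENSBTAG00000049252	1.456705	0.021729	-2.04834	0.038247
ENSBTAG00000020657	1.181837	0.030384	-1.56274	0.026203
ENSBTAG00000008102	-3.03056	1.25E-08	3.557471	0.000873
ENSBTAG00000004574	-1.29523	0.029759	1.617777	0.036439
ENSBTAG00000016713	-1.24634	0.004976	1.390926	0.048112
ENSBTAG00000022807	-1.11625	0.016776	2.249306	0.010536
ENSBTAG00000021672	-1.7669	0.015431	-2.57396	0.003803
ENSBTAG00000010303	-3.1629	0.004747	-1.36418	0.019584
ENSBTAG00000050334	-2.23789	0.031922	-2.32905	0.028488
ENSBTAG00000014861	-1.1557	0.00036	-1.05887	0.036691
ENSBTAG00000006383	-3.57022	0.00157	-2.7064	0.005605
ENSBTAG00000042458	-1.67516	0.025334	-3.67905	0.001893
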