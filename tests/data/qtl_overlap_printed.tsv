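chrom	lnc_start	lnc_end	transcript	qtl_start	qtl_end	trait	qtl_id
17	61378380	61395414	MSTRG.9569.1	61449556	61449560	Somatic cell score	32454
17	71135959	71143749	MSTRG.9863.25	71223822	71223826	Somatic cell count	154834
17	71135959	71143749	MSTRG.9863.25	71238170	71238174	Somatic cell count	154835
18	55476038	55476403	MSTRG.11108.1	55440944	55440948	Somatic cell score	49858
18	56357208	56358053	MSTRG.11174.7	56318522	56318526	Somatic cell count	154910
18	62625500	62714586	MSTRG.11478.1	62806228	62806232	Somatic cell score	49936
19	51101532	51105796	MSTRG.12937.1	51070944	51070948	Somatic cell score	32254
19	56816326	56846862	MSTRG.13184.1	56757235	56757239	Clinical mastitis	36516
2	106176194	106184237	MSTRG.14160.1	106216096	106216100	Clinical mastitis	32505
5	30135703	30140607	MSTRG.24855.2	30041934	30041938	Clinical mastitis	161585
5	43266426	43268842	MSTRG.25021.1	43337889	43337893	Somatic cell score	175697
9	36961562	36963701	MSTRG.30297.1	37050843	37050847	Somatic cell score	32400
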