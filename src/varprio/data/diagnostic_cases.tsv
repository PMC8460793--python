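case_id	sex	event_class	finding	coordinates	printed_size	prior_exome	prior_microarray
0703	M	sv_translocation	t(1;9) de novo translocation	chr1:49553194|chr9:29096674		yes	yes
5103	M	sv_deletion	TANGO2 biallelic deletion	chr22:20039637-20075714|chr22:20041469-20075432	36 kb	yes	yes
4203	M	sv_deletion	WAC deletion, de novo	chr10:28615989-28617469	1480 bp	yes	yes
4803	F	sv_deletion	USP34 deletion, de novo	chr2:61210747-61215747	5000 bp	yes	yes
2403	F	small_variant	TSPEAR compound het	 	 	yes	no
1003	M	small_variant	INTS1 compound het	 	 	yes	yes
1903	M	small_variant	MMAB hom; PHF8 de novo mosaic	 	 	yes	no
0803	M	small_variant	ATRX de novo mosaic	 	 	yes	yes
1703	F	sv_duplication	NHEJ1 duplication, de novo	chr2:219102933-219134970	32 kb	no	yes
2303	F	sv_duplication	4p16.3 duplication, de novo	chr4:446930-749753	303 kb	no	yes
3103	F	small_variant	SMAD4 de novo het	 	 	no	yes
0103	F	small_variant	RPS6KA3 de novo het	 	 	no	yes
0203	M	small_variant	MAP2K1 de novo het	 	 	no	yes
0503	F	small_variant	KCNB1 de novo het	 	 	no	yes
1503	F	small_variant	LHX3 hom; OGDH hom	 	 	no	yes
2103	F	small_variant	LONP1 de novo het; BCKDHA hom	 	 	no	yes
2704	M	small_variant	FRAS1 compound het	 	 	no	yes
3603	M	small_variant	NECTIN1 hom	 	 	no	yes
4103	F	small_variant	ACAN frameshift	 	 	no	yes
4903	F	small_variant	COL4A3 missense	 	 	no	yes
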