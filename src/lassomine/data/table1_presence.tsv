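genome_label	bagel4_lasA	bagel4_lasB	bagel4_lasC	bagel4_lasD	antismash5_lasA	antismash5_lasB	antismash5_lasC	antismash5_lasD
Acetitomaculum ruminis DSM 5522	0	0	1	1	0	1	1	1
Actinomyces denticolens PA	1	0	1	1	0	0	0	0
Bacillus cereus KPR-7A	0	0	0	0	1	1	1	1
Bacillus licheniformis VTM3R78	0	0	1	1	1	1	1	1
Bacillus sp. MB2021	0	0	1	1	1	1	1	1
Butyrivibrio fibrisolvens AB2020	1	0	1	0	0	1	1	1
Butyrivibrio fibrisolvens AR40	0	0	1	0	0	1	1	0
Butyrivibrio fibrisolvens DSM 3071	0	0	1	0	1	1	1	1
Butyrivibrio fibrisolvens MD2001	0	0	0	1	0	1	1	1
Butyrivibrio fibrisolvens WTE3004	0	0	1	0	0	1	1	1
Butyrivibrio fibrisolvens YRB2005	0	0	1	0	0	1	1	1
Butyrivibrio proteoclasticus B316	0	0	1	1	0	1	1	1
Butyrivibrio proteoclasticus FD2007	0	0	1	1	0	1	1	1
Butyrivibrio sp. FC2001	0	0	1	0	0	1	1	0
Butyrivibrio sp. INlla14	0	0	0	0	0	1	1	1
Butyrivibrio sp. MC2021	0	0	1	1	0	1	1	1
Butyrivibrio sp. NC3005	0	0	1	1	0	1	1	1
Butyrivibrio sp. VCD2006	0	0	1	1	1	1	1	0
Butyrivibrio sp. XBB1001	0	0	1	1	0	1	1	1
Butyrivibrio sp. XPD2006	0	0	1	0	0	1	1	1
Butyrivibrio sp. YAB3001	0	0	1	1	0	1	1	1
Clostridium beijerinckii HUN142	0	0	1	0	0	1	1	1
Clostridium butyricum AGR2140	0	0	1	1	0	1	1	1
Eubacterium celullosolvens LD2006	0	0	0	0	0	1	1	0
Lachnospira multipara D15d	0	0	1	1	1	1	1	1
Lachnospira multipara LB2003	0	0	1	1	0	1	1	1
Lachnospira multipara MC2003	0	0	1	1	1	1	1	1
Lachnospira multipara ATCC 19207	0	0	0	0	1	1	1	1
Lachnospira pectinoschiza M83	0	0	1	1	0	1	1	1
Lachnospiraceae bacterium KH1P17	0	0	0	0	0	1	1	0
Lachnospiraceae bacterium MA2020	0	0	1	1	0	1	1	1
Lachnospiraceae bacterium YSD2013	0	0	1	0	0	1	1	0
Ruminococcus albus 8	0	0	0	0	1	1	1	1
Ruminococcus flavefaciens ATCC 19208	1	0	0	1	1	1	1	1
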