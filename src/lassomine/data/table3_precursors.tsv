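entry_label	leader	core	printed_core_length	recomputed_core_length	multiplicity
Bacillus cereus KPR-7A	MKKDWTIPTLEVLDINMTMA	GPGLKTPDAVQPDVDEVVHYS	21	21	1
Butyrivibrio fibrisolvens AB2020	MKAWNTPVIETLEINETAA	GGRQVTSHDGNIRVDNGIPAEEYLSGPVER	29	30	1
Butyrivibrio fibrisolvens AR40	MKVWNAPVMESLEINETAK	GGKKVSEHDGFINYSHNGLPAEEYASGPVAK	31	31	1
Butyrivibrio fibrisolvens DSM 3071	MKAWNTPVMESLEINETAG	GYNQITEHDGVINYSAGIPAEEYASGPLPR	30	30	1
Butyrivibrio fibrisolvens MD2001	MKVWNAPVMESLEINETAK	GGKKVSEHDGFINYSHNGLPAEEYASGPVAK	31	31	1
Butyrivibrio fibrisolvens WTE3004	MKAWNTPVIETLEINETAA	GGRQVTSHDGNIRVDNGIPAEEYLSGPVER	30	30	1
Butyrivibrio fibrisolvens YRB2005	MKAWNTPVIETLEINETAA	GGRQVTSHDGNIRVDNGIPAEEYLSGPVER	30	30	1
Butyrivibrio proteoclasticus B316	MKNWNAPEIKELCLSGTQQH	GTPNPYVDGKIYDAQRNENWFTFSGNNVDDTATPGEVIIGNP	42	42	1
Butyrivibrio proteoclasticus FD2007	MKNWNTPEIKELSLSGTQLH	GQDVRFVDGSIYDEERNTNWASYSGGRPNRDEQPGEVIIH	40	40	1
Butyrivibrio sp. FC2001	MKKVWNDATLEALDITATAG	GIYDTEELDSEKWFDEEHKQWWGSFGNNNLSKAKKED	37	37	1
Butyrivibrio sp. INlla14	MKTWNSAEIVELALNQTAG	GSFDITTHDGKIVYTTLANGRQVPSEQYAYVSGEQHA	37	37	1
Butyrivibrio sp. MC2021	MKNWNAPEIQELNLSNTEL	GNRRSGYCDAAVWSVELHKNFYSYSGEGDPNEDEWNVHPQH	41	41	1
Butyrivibrio sp. NC3005 (#1, #2)	MKWNAPVMEELNINATAN	GMAPDENFDGDWVEINGKWYRPGNGSVSGGEIAQ	34	34	2
Butyrivibrio sp. NC3005 (#3)	MKWNAPVMEELNINATAN	GMAPDENFDGDWVEINGRWYRPGNGSISGSETAH	34	34	1
Butyrivibrio sp. VCD2006	MKKWNAPNIQELNLSSTMLR	GRNPKYVDGYVYDAERDTNWASYSGGTSDPSATGAEVIINNP	42	42	1
Butyrivibrio sp. XBB1001	MKTWTSPEIKELNISNTAL	GNARSGYCDAAVYSIELHRNFYSFSGEGEKNQDDWHVTPQNP	42	42	1
Butyrivibrio sp. XPD2006	MKTWVNPEVVELEISATAQ	GDGPIAIPDAIRVDNDGTWYSFPSGSSQDAQ	31	31	1
Butyrivibrio sp. YAB3001 (#1)	MKTWLDAVIEEINFEKTED	GRSEKLDNDRQYTDGRGLAIQLGGHLS	27	27	1
Butyrivibrio sp. YAB3001 (#2)	MKAWNTPVIEEVKFTATKE	GSQQWQVPDKHYLDETDNQWKWEFSDGKLN	30	30	1
Clostridium beijerinkii HUN142	MNETKLKWSEPEVMDLSVKDTQL	GGHYSSSPDGAPWQDSNGNWQEPHGKS	18	27	1
Eubacterium celullosolvens LD2006	MKKWVNPEFKVLNISKTTY	GPWNQTIPDSELTAEFDEFGNVKGYRQLFGQASGTTGETGTPAV	44	44	1
Lachnospira multipara D15d	MKTWITPRVEELEIVETAQ	GKSIKPSFDAFRIDENGNLWASFES	25	25	1
Lachnospira multipara LB2003 (#1)	MRTWTKPEVEVLAIAETAQ	GKVIKASFDAIRTDVNGNLWVSFPSGAEE	28	29	1
Lachnospira multipara LB2003 (#2)	MKTWITPAVEELEIVETAQ	GKNIKPSFDELRVDANGNLWASFQS	25	25	1
Lachnospira multipara MC2003	MKTWITPAVEELEIVETAQ	GKNIKPSFDELRVDANGNLWASFQS	25	25	1
Lachnospira multipara ATCC 19207	MKTWITPRVEELEIVETAQ	GKSIKPSFDAFRIDENGNLWASFES	25	25	1
Lachnospira pectinoschiza M83 (#1)	MKTWTKPELEVLAIEETAQ	GKVIKPSFDSVRTDENGNLWASFPSGAEE	29	29	1
Lachnospira pectinoschiza M83 (#2)	MRTWTTPELEVLEITETAQ	GKVIKASFDAIRTDENGNLWVSFPSGAED	29	29	1
Lachnospiraceae bacterium KH1P17	MRKWNTPELQELAINATAG	GPQDNHTEDGKTVYDHEENAWYHRFGEDGNYTRN	34	34	1
Lachnospiraceae bacterium MA2020	MKSWNTPAIEELNINETAG	GGQKTMNWDGEWITPDEGKSWWAGTVIVSG	30	30	1
Lachnospiraceae bacterium YSD2013 (#1)	MKKFEVAELVVLNIADTAF	GPDDPNHVDDYKHAVEDPITHEVLGYEEEYGQAHSSNQN	39	39	1
Lachnospiraceae bacterium YSD2013 (#2)	MKKFVNADIQEVAIEETAF	GPLNPEDVDETKYAVTDEEGNIIGYRAKFGKADASRQ	37	37	1
Ruminococcus albus 8	MTYNKPSFEKISSFKESTM	GVWFGKFKDIFGGKAVVEIVIYY	23	23	1
Ruminococcus flavefaciens ATCC 19208 (#1)	MTYNKPSVEKVASFKDNTM	GLWYGKFRDIFGAKTYFNLAWN	22	22	1
Ruminococcus flavefaciens ATCC 19208 (#2)	MTYNKPSFEKVASFKNKTM	GLWFGNFKDLFGGKIYIALSPAW	23	23	1
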