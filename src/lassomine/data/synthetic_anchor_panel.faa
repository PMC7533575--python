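>lasB_ref_syn synthetic leader-peptidase (transglutaminase-homolog) anchor query
MSFGLFHCVLDNLGLTLELSNAPSFVDDYQADAVKFNDALMSWIRQNSRPPARFSGNTFF
LSIKLINILHEYESRVKFFALLYHTDPVLESEFIILWTSKLNFVAYGAARHSTRSFIETV
PLYVYGGNNW
>lasC_ref_syn synthetic lasso-cyclase (asparagine-synthetase-homolog) anchor query
MSYIASRSGVIAYEVRLPWSSSFLASEEVRTGTPLQKKGHESKRSLQTEVRLSGIPTFTH
TTGAIYFFGHKYMPGVDEEIQKPGAEKALAAADPEPLGLTESPLKPKHGLALQQGSGELT
SALRLEPPETVKLALDLSSVAFPHSREQAIMLRISIGWDKDGMVYYGATNSRWDRINFGE
KGLFKRKSLSNLKAIKLKLDRRDVPKIFEY
>lasD_ref_syn synthetic ABC-transporter anchor query
MAFFIDQVYQSEAFTSEQKYFEADVSVLFDHANTFPKKKSEPAQLRCTLTFSIFVDVGLA
SRPKPQLEFYVLEQIVMLRKILFIANLYDPPAADISYWRILGLSFAEWIGGWVATMAGYL
LNGCALEIYETTSFFSKQNPQMTMEPVRIIANPVSAMARD
>lasA_ref_syn synthetic precursor anchor query
MYGRVQVSSTNLGLGFITHAAYIQTQKLQRRLVKMVVDQPMLLL
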