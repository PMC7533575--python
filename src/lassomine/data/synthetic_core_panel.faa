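>core_syn_001 synthetic known-core panel entry
GARVIAPGDKPKDNDDIRSPESQLD
>core_syn_002 synthetic known-core panel entry
GGKWEQKIDLLIQMYLSKSRLKTG
>core_syn_003 synthetic known-core panel entry
GRPGPTADPMVELRINVVER
>core_syn_004 synthetic known-core panel entry
GMGIAWVIDTWYGFVEDLEREEK
>core_syn_005 synthetic known-core panel entry
GYLGIKQADVYLTYAYSVFL
>core_syn_006 synthetic known-core panel entry
GIPQPKDDLTGSDHGKRE
>core_syn_007 synthetic known-core panel entry
GTIPGVQEDYQLVLYDVEDDDLQ
>core_syn_008 synthetic known-core panel entry
GRTKEQEDYGLLTGK
>core_syn_009 synthetic known-core panel entry
GLANQDADDITFLMSCENALLIRDL
>core_syn_010 synthetic known-core panel entry
GAAQWAQDLAAKKSNTWQKKVAVS
>core_syn_011 synthetic known-core panel entry
GLGGDKLNDIFINPTDLCV
>core_syn_012 synthetic known-core panel entry
GTPHGMFFDTLTPSVTKELN
>core_syn_013 synthetic known-core panel entry
GIVGKLSDATMIITK
>core_syn_014 synthetic known-core panel entry
GVYSEEASDFVIKLIIEAEIIEDLE
>core_syn_015 synthetic known-core panel entry
GIQHSSRDDVMMNATY
>core_syn_016 synthetic known-core panel entry
GRPTKGNQDKRSFKA
>core_syn_017 synthetic known-core panel entry
GIAAELGRDSAIHLLKSSDIPKEAY
>core_syn_018 synthetic known-core panel entry
GKSIIYIDEGVKRELRAYL
>core_syn_019 synthetic known-core panel entry
GGARDTEDGDKGGGTKFTVIFEIIL
>core_syn_020 synthetic known-core panel entry
GRINTGTDADVIMFRVLCALDLFYI
>core_syn_021 synthetic known-core panel entry
GDHKVAGDLSQSLAPMVSHTKWF
>core_syn_022 synthetic known-core panel entry
GVFDVNQDREKRKPQVRFTKKLA
>core_syn_023 synthetic known-core panel entry
GVWDKVANDYETVNSV
>core_syn_024 synthetic known-core panel entry
GWIMIPGDYIVTGAPGAIESYA
>core_syn_025 synthetic known-core panel entry
GNVMIQVVDIQRILKGG
>core_syn_026 synthetic known-core panel entry
GADQELTDRPNTLIVAVFRADD
>core_syn_027 synthetic known-core panel entry
GFKLAAIDTTDVQLY
>core_syn_028 synthetic known-core panel entry
GERSMSEDKKAAGLFYSQGV
>core_syn_029 synthetic known-core panel entry
GQLGGSKDGYKSNLVFLDGRYHD
>core_syn_030 synthetic known-core panel entry
GRSYANNDSKENKAKRK
>core_syn_031 synthetic known-core panel entry
GKQIADMDELICQMG
>core_syn_032 synthetic known-core panel entry
GEGRIMIRDYRVKKNG
>core_syn_033 synthetic known-core panel entry
GLYTERETDKHSGQAEPKV
>core_syn_034 synthetic known-core panel entry
GRVAQVIIDKEVIAPVFDRF
>core_syn_035 synthetic known-core panel entry
GSIKQGTGDEMSKMGVTIVIE
>core_syn_036 synthetic known-core panel entry
GAFVILLDVEVKEIVE
>core_syn_037 synthetic known-core panel entry
GKRFCEDDIVQQGMPVMIGF
>core_syn_038 synthetic known-core panel entry
GTTIKQGVDNLYPAAKYHATVEC
>core_syn_039 synthetic known-core panel entry
GGHYLDHKDADRVLKAGAQAFQISA
>core_syn_040 synthetic known-core panel entry
GDYQVNLDTQGNTKLRIKEVTGS
>core_syn_041 synthetic known-core panel entry
GANKGGAFDEGLEKFATRVQ
>core_syn_042 synthetic known-core panel entry
GGAGAGPDIVTCSDDPRHEGEL
>core_syn_043 synthetic known-core panel entry
GFQEAFVPDLTEEIVPGKFYHA
>core_syn_044 synthetic known-core panel entry
GLSVKHKDTLGATEQTQLA
>core_syn_045 synthetic known-core panel entry
GTAKLARDKDWLVFGAGSYKEI
>core_syn_046 synthetic known-core panel entry
GRRAIGADQQNGVDGGE
>core_syn_047 synthetic known-core panel entry
GGPVVGADNGIMLASKMHNL
>core_syn_048 synthetic known-core panel entry
GIIFNETEDPSDYDECLQSKPTNLG
>core_syn_049 synthetic known-core panel entry
GSANNKVYDSYYRLAMEMI
>core_syn_050 synthetic known-core panel entry
GGKETKGDKIQEVTPY
>core_syn_051 synthetic known-core panel entry
GNANGIWDLNVQGKWVAAT
>core_syn_052 synthetic known-core panel entry
GRNPKLADDTNAKTVGILV
>core_syn_053 synthetic known-core panel entry
GVLTLILEDSMQSIRGIVGVPFSD
>core_syn_054 synthetic known-core panel entry
GTIYEEGDRDSLGFVVIA
>core_syn_055 synthetic known-core panel entry
GLFALVIKDKTILKIMVKMERED
>core_syn_056 synthetic known-core panel entry
GMYSTVEADQYIGKLNGISGTY
>core_syn_057 synthetic known-core panel entry
GAQTAQYTDGQETVIDVQEYKRKS
>core_syn_058 synthetic known-core panel entry
GGSKPKTDYIRLSQPGEV
>core_syn_059 synthetic known-core panel entry
GATDHQVIDDANDKHFPKLM
>core_syn_060 synthetic known-core panel entry
GAFFFQEDFGPVGATNPALHPY
>core_syn_061 synthetic known-core panel entry
GRVLEQVDSLSYKVTTT
>core_syn_062 synthetic known-core panel entry
GLNEATRKDHDRRKTGTAGQ
>core_syn_063 synthetic known-core panel entry
GIIPGGWDAHVPDYLQVG
>core_syn_064 synthetic known-core panel entry
GQTNNKWDQQKAQFEATSSF
>core_syn_065 synthetic known-core panel entry
GTYTYILDGIKLIRKAQSPI
>core_syn_066 synthetic known-core panel entry
GCYIDQPDEPSIVNATH
>core_syn_067 synthetic known-core panel entry
GAKTVIMVDAELLHSSYNTDTFVT
>core_syn_068 synthetic known-core panel entry
GTLPITYDGCFENEQLVSGLDH
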