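accession	sequence	reported_mass
sp|P00780|SUBC_BACLI	AAGNSGSSGNTNTIGYPAKY	1928.89
sp|P00780|SUBC_BACLI	AQTVPYGIPLIK	1298.76
sp|P00780|SUBC_BACLI	AQTVPYGIPLIKADKVQAQ	2039.14
sp|P00780|SUBC_BACLI	ASHPDLNVVGGA	1135.56
sp|P00780|SUBC_BACLI	ASHPDLNVVGGAS	1222.59
sp|P00780|SUBC_BACLI	AVDSNSNRASFS	1253.56
sp|P00780|SUBC_BACLI	AYNTDGNGHGTHVA	1413.59
sp|P00780|SUBC_BACLI	DNTTGVLGVAPSVSLY	1591.81
sp|P00780|SUBC_BACLI	DTGIQASHPDLNVVGGA	1649.80
sp|P00780|SUBC_BACLI	GAVDSNSNRASFS	1310.59
sp|P00780|SUBC_BACLI	GIPLIKADKVQAQ	1379.81
sp|P00780|SUBC_BACLI	ILSKHPNLSAS	1165.65
sp|P00780|SUBC_BACLI	NSSGSGSYSGIVSGIE	1499.67
sp|P00780|SUBC_BACLI	NSSGSGSYSGIVSGIEWATTN	2072.93
sp|P00780|SUBC_BACLI	NTDGNGHGTHVA	1179.49
sp|P00780|SUBC_BACLI	SLGGASGSTAMKQ	1209.57
sp|P00780|SUBC_BACLI	STYPTNTYATL	1230.58
sp|P00780|SUBC_BACLI	STYPTNTYATLN	1344.62
sp|P00780|SUBC_BACLI	VDSNSNRASFS	1182.53
sp|O16808|ACT_MAYDE	AGDDAPRAVFPS	1201.57
sp|O16808|ACT_MAYDE	GFAGDDAPRAVFPS	1405.66
sp|O16808|ACT_MAYDE	GQKDSYVGDEAQSKRGILTL	2164.11
sp|O16808|ACT_MAYDE	KSYELPDGQVITIG	1518.79
sp|O16808|ACT_MAYDE	KSYELPDGQVITIGNE	1761.88
sp|P80057|GSEP_BACLD	SEPIGNTVGYF	1182.56
sp|P80057|GSEP_BACLD	WQHSGPIAISE	1223.59
sp|P02461|CO3A1_HUMAN	GEPGQAGPSGPPGPPGAIGPSGP	1937.91
sp|Q8RB67|DNAJ_CALS4	GEGEPGLRGGPN	1139.52
sp|Q9BXJ0|C1QT5_HUMAN	GEAGPAGPTGPAG	1037.48
sp|B4UGJ6|Y4073_ANASK	EGAVALGAGLALGGSRE	1526.81
sp|O45218|ADAS_CAEEL	LDPANIFASANLIDI	1585.84
sp|Q03A18|ATPB_LACP3	GDPIDGGEAFGP	1130.49
sp|A5WGE2|LPXA_PSYWF	IGNNVILGGNAG	1097.58
sp|O60784|TOM1_HUMAN	SAEGPPGPPSGPA	1119.52
sp|P45586|CU79A_LOCMI	LGGGLGGIGL	812.48
sp|O24385|CPI7_SOLTU	VDDDKDFIPF	1209.56
sp|Q38YA9|GPDA_LACSS	MPITNAIYNVL	1247.66
sp|Q5RF96|SPCS1_PONAB	SGAVAIAFPGLEGPPA	1452.76
sp|P54334|XKDO_BACSU	GGGLVGGI	628.35
sp|Q75JF3|CLCC_DICDI	LIGGLLG	641.41
sp|Q3UHE1|PITM3_MOUSE	AGPSGDSPGSSSR	1142.50
sp|Q8IQG1|MOB2_DROME	LLGGILG	641.41
sp|Q38XN0|MRAY_LACSS	IIGGLIG	641.41
sp|A4R2R1|NST1_MAGO7	NQHYPPGIGPLNAP	1490.72
sp|L0E307|PHQO_PENFE	YLKPVPIVPGLP	1319.79
sp|Q80XI7|VOME_MOUSE	GGLGIGGLL	755.45
sp|Q8BM72|HSP13_MOUSE	VTGVAIQAGIDGGSWP	1526.77
sp|C1A8U3|DAPF_GEMAT	FVKMTGSGNDF	1233.53
sp|P80057|GSEP_BACLD	GYPGDKTAGTQWQHSGPIAISE	2299.09
sp|O42350|CO1A2_LITCT	AGLNGGLGPSGPA	1067.52
sp|P00780|SUBC_BACLI	SHPDLNVVGGA	1064.53
sp|P00780|SUBC_BACLI	AAGNSGSSGNTNTIGYPA	1637.73
sp|Q5FRT2|PROA_GLUOX	LIDAAIAPAL	966.58
sp|P00780|SUBC_BACLI	SKHPNLSAS	939.48
sp|P00780|SUBC_BACLI	APGAGVY	633.31
sp|Q9M3B0|PME34_ARATH	MPVSQIQADIIV	1314.67
sp|Q9Z470|AROA_CORGL	ATAGAIIGLAVDG	1127.62
sp|A1XGT3|TI214_RANMC	LIVLPSLI	866.58
sp|D4GP41|KGSDH_HALVD	GATLVAGGGVPE	1026.53
sp|Q8X226|CAS1_CRYNH	FGLWVLNWI	1147.61
sp|Q9C6V3|AGL86_ARATH	AGAGAGAAPL	754.40
sp|P27483|GRP1_ARATH	GAGGGLGGGHGGGIGGGAGGGSGGGLGGGIGGGAGG	2447.13
sp|P27393|CO4A2_ASCSU	GDDGLPGAPGRPG	1146.54
sp|P00780|SUBC_BACLI	NSSGSGSYSGIVS	1200.53
sp|B2A865|ACCDA_NATTJ	EGGSGGALALTV	1030.53
sp|Q8WXI7|MUC16_HUMAN	PSLLSLPATTSP	1182.65
sp|Q9H7P9|PKHG2_HUMAN	RGGGGGGPR	769.39
sp|Q1HVF7|EBNA1_EBVA8	GAGGGAGAGGGAGAGGGAGAGGGAG	1555.67
sp|Q80XI7|VOME_MOUSE	GGEGGGLGIGGLL	1055.56
sp|Q7W0A6|MUTL_BORPE	AGVPDGAAPDTAYAGEPA	1628.73
sp|Q8IA41|GLT11_DROME	EPILLNNQ	939.50
sp|Q8K4I4|BPIA1_RAT	NGLVGGLLG	798.46
sp|B8ITX3|MCH_METNO	VAEAAGVPL	825.46
sp|Q9LEJ0|ENO1_HEVBR	SIEDPFDQD	1064.43
sp|P86950|SLP2_PINMA	GIGGGGIIGGGPI	1023.57
sp|Q5U9X3|GPC6A_DANRE	IIGGLFPI	828.51
sp|Q9NG98|TOP3A_DROME	GGGGGPGPGPGGG	879.38
sp|O16808|ACT_MAYDE	RVAPEEHPVLL	1258.70
sp|P34804|COL40_CAEEL	SEPGPAGPAGDAGPDGAPGNAGAPGA	2114.91
sp|Q2KIN5|HEM3_BOVIN	WSLNGAETMQ	1136.48
sp|Q9FZC4|FOX1_ARATH	PAGTPKTVLLGRP	1305.78
sp|P12575|FUS_SENDF	IVVMVVIL	884.58
sp|B0TMM7|ADEC_SHEHH	LDALAPLI	824.50
sp|P00780|SUBC_BACLI	SHPDLNVVGGAS	1151.56
sp|P49597|P2C56_ARATH	AGPFRPF	790.41
sp|Q7TZN1|PKNF_MYCBO	TEAPLPIE	868.45
sp|Q6AZY7|SCAR3_HUMAN	GDPGSLGPLGPQ	1094.52
sp|P17140|CO4A2_CAEEL	QDGLPGLPGNKG	1152.58
sp|A5G0G6|LEUC_ACICJ	LGMNPDKLKPGE	1297.67
sp|Q7SIB2|CO4A1_BOVIN	GPAGVPGLPGAKGDHGFPGSSGPRGD	2343.14
sp|Q96MP8|KCTD7_HUMAN	FGDVLNF	810.39
sp|Q8TZZ2|MPTA_PYRFU	EDIALEDMI	1047.48
sp|Q7Z5A4|PRS42_HUMAN	APGPEAGPPL	904.47
sp|O48534|DEXHD_ARATH	VQVGVAINGE	984.52
sp|Q9QY06|MYO9B_MOUSE	DAGLSPGSQGDSK	1217.55
sp|Q4K758|SYM_PSEF5	ITQYFDPE	1011.45
sp|Q9Y4K4|M4K5_HUMAN	SSDPNFMLQ	1038.43
sp|Q8SWH6|Y206_ENCCU	DVPVEEMAVG	1044.48
sp|Q82EX7|DNAJ1_STRAW	GAGGGFGGGI	748.35
sp|B2GDS9|DNLJ_LACF3	AGDIIPE	713.36
sp|Q9Z8N1|PHSG_CHLPN	AIEDIALI	856.49
sp|Q9FCC1|BIOD_STRCO	GAPLLGAVPAGAGS	1136.62
sp|Q6CZR3|GPH_PECAS	IGGDDVIVK	914.51
sp|P0C062|GRSA_BREBE	GGEGLARGYWK	1192.60
sp|P21840|VSM5_TRYBR	GEDQETFHSRFWDQ	1781.73
sp|Q97CT6|METK_THEVO	DTSFGVGFAP	996.46
sp|Q2KJ58|R3GEF_BOVIN	SVGPCKSHRESLGGLPE	1751.86
sp|Q10Y85|RIMO_TRIEI	GTPAYNLPN	945.46
sp|Q4K5F9|PROA_PSEF5	NEVDSSSVMVNASTRF	1741.79
sp|D5AV94|TKT_RHOCB	FVGMEGFGASAPA	1239.56
sp|Q9KPI4|Y2383_VIBCH	AAAQLALGGML	1014.55
sp|Q8SY41|BCAS3_DROME	GLGVQVWAIPANGEAVE	1708.88
sp|Q9DD48|MKRN2_SERQU	GGGGAGGGGAGIGGAGGGP	1239.56
sp|O48928|C77A3_SOYBN	TALAFFISGLIF	1298.73
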