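# Circular signed gene orders for the scale-insect gene-order comparison.
# PARTLY SYNTHETIC: the ancestral pancrustacean arrangement and the Putoidae
# order (from the reference feature table) are real; for the other 17 taxa only
# the literature-stated diagnostic clusters are real (trnM-ND2-trnW in the four
# non-neococcoids; trnI-ND2-trnY, trnY-ND2-trnW, trnI-ND2-trnW, trnQ-ND2-trnW
# in the named neococcoids; trnY relocation in Matsucoccidae; trnH-ND1-trnL1
# and ND4-trnP-rrnS-trnT-cytb-trnS2 in Monophlebidae) — the remainder of each
# order is synthetic filler and its pairwise distances carry no evidential
# weight. Leading "-" marks the minority (N) strand.
taxon	group	order
ancestor	ancestor	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,-trnQ,trnM,ND2,trnW,-trnC,-trnY
Matsucoccus_matsumurae	non_neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,-trnQ,trnM,ND2,trnW,-trnY,-trnC
Icerya_purchasi	non_neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND1,-trnL1,-ND4,-trnP,-srRNA,trnT,cytb,trnS2,-ND4L,ND6,-lrRNA,-trnV,trnI,-trnQ,trnM,ND2,trnW,-trnC,-trnY
Coronaproctus_castanopsis	non_neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND1,-trnL1,-ND4,-trnP,-srRNA,trnT,cytb,trnS2,-ND4L,ND6,-lrRNA,-trnV,trnI,-trnQ,trnM,ND2,trnW,-trnC,-trnY
Putosinensis	non_neococcoid	COI,trnL2,trnD,ATP8,ATP6,COIII,trnA,trnR,trnN,trnE,-trnF,-trnH,ND6,trnS1,-trnQ,-ND1,-trnL1,-lrRNA,-trnV,trnI,trnM,ND2,trnW,-trnY,COII,trnK,trnG,ND3,trnS2,-ND5,-ND4,-ND4L,trnT,-trnP,-trnC,cytb,-srRNA
Paracoccus_marginatus	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,trnW,-trnY,-trnQ,trnM,-trnC
Phenacoccus_aceris	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,-trnY,ND2,trnW,trnI,-trnQ,trnM,-trnC
Phenacoccus_manihoti	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Acanthococcus_coriaceus	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,trnW,-trnY,-trnQ,trnM,-trnC
Apiomorpha_munita	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,-trnQ,ND2,trnW,trnI,-trnY,trnM,-trnC
Albotachardina_sinensis	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Antecerococcus_theydoni	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Nipponaclerda_biwakoensis	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Aclerda_takahashii	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Didesmococcus_koreanus	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Saissetia_coffeae	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Parasaissetia_nigra	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Ceroplastes_japonicus	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
Ceroplastes_floridensis	neococcoid	COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,cytb,trnS2,-ND1,-trnL1,-lrRNA,-trnV,-srRNA,trnI,ND2,-trnY,-trnQ,trnM,trnW,-trnC
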