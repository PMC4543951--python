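group,taxon,life_stage,autumn_n,autumn_pct,spring_n,spring_pct
Arachnida,Acarina,,58,3.69,165,7.05
Arachnida,Araneae,,194,12.36,92,3.93
Arachnida,Opiliones,,14,0.89,6,0.26
Arachnida,Pseudoscorpiones,,21,1.34,20,0.85
Miriapoda,Symphila,,0,0,0,0
Miriapoda,Diplopoda,,5,0.32,0,0
Miriapoda,Chilopoda,,4,0.25,1,0.04
Hexapoda,Protura,,0,0,0,0
Hexapoda,Diplura,,0,0,1,0.04
Hexapoda,Collembola,,1122,71.46,1899,81.08
Hexapoda,Coleoptera,larvae,14,0.89,4,0.17
Hexapoda,Coleoptera,adults,13,0.83,24,1.02
Hexapoda,Diptera,larvae,27,1.72,3,0.13
Hexapoda,Diptera,adults,25,1.59,60,2.56
Hexapoda,Lepidoptera,larvae,0,0,7,0.3
Hexapoda,Lepidoptera,adults,1,0.06,0,0
Hexapoda,Hymenoptera,,27,1.72,8,0.34
Hexapoda,Formicidae,,1,0.06,4,0.17
Hexapoda,Embioptera,,0,0,0,0
Hexapoda,Dermaptera,,0,0,0,0
Hexapoda,Hemiptera,,28,1.78,23,0.98
Hexapoda,Orthoptera,,0,0,1,0.04
Hexapoda,Trichoptera,,0,0,0,0
Mollusca,Gasteropoda,,3,0.19,1,0.04
Crustacea,Isopoda,,13,0.83,23,0.98
Anellida,Lumbricidae,,0,0,0,0
Nematomorpha,Gordioida,,0,0,0,0
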