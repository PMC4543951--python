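group,taxon,life_stage,autumn_n,autumn_pct,spring_n,spring_pct
Arachnida,Acarina,,355,23.86,622,26.63
Arachnida,Araneae,,57,3.83,17,0.73
Arachnida,Opiliones,,22,1.48,5,0.21
Arachnida,Pseudoscorpiones,,16,1.08,5,0.21
Miriapoda,Symphila,,1,0.07,5,0.21
Miriapoda,Diplopoda,,16,1.08,32,1.37
Miriapoda,Chilopoda,,17,1.14,12,0.51
Hexapoda,Protura,,7,0.47,0,0
Hexapoda,Diplura,,0,0,3,0.13
Hexapoda,Collembola,,411,27.62,788,33.73
Hexapoda,Coleoptera,larvae,40,2.69,26,1.11
Hexapoda,Coleoptera,adults,42,2.82,81,3.47
Hexapoda,Diptera,larvae,6,0.40,71,3.04
Hexapoda,Diptera,adults,233,15.66,459,19.65
Hexapoda,Lepidoptera,larvae,5,0.34,22,0.94
Hexapoda,Lepidoptera,adults,28,1.88,5,0.21
Hexapoda,Hymenoptera,,47,3.16,36,1.54
Hexapoda,Formicidae,,88,5.91,18,0.77
Hexapoda,Embioptera,,2,0.13,0,0
Hexapoda,Dermaptera,,1,0.07,0,0
Hexapoda,Hemiptera,,50,3.36,46,1.97
Hexapoda,Orthoptera,,2,0.13,0,0
Hexapoda,Trichoptera,,1,0.07,0,0
Mollusca,Gasteropoda,,20,1.34,17,0.73
Crustacea,Isopoda,,4,0.27,27,1.16
Anellida,Lumbricidae,,14,0.94,39,1.67
Nematomorpha,Gordioida,,3,0.20,0,0
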