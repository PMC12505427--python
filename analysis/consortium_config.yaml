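# Synthetic consortium emulating the genomic regimes of a cixiid
# planthopper's co-primary endosymbionts: three small, extremely AT-rich
# circular genomes with complementary nutritional gene repertoires.
genomes:
  karelsulcia_sim:          # branched-chain amino-acid specialist
    seed: 42
    genome_length: 130000
    gc_target: 0.26
    n_genes: 140
    n_snps_pair: 2          # near-identical genome pair regime
    pathway_assignment:
      isoleucine: [ilvI, ilvC, ilvD, ilvE]
      leucine: [leuA, leuC, leuD, leuB]
  vidania_sim:              # provider of the seven other EAAs
    seed: 43
    genome_length: 136000
    gc_target: 0.19
    n_genes: 150
    n_snps_pair: 68
    pathway_assignment:
      lysine: [lysC, asd, dapA, dapB, dapD, argD, dapE, dapF, lysA]
      threonine: [thrA, thrB, thrC]
      methionine: [metC, metE]
      arginine: [carA, carB, argF, argG, argH]
      histidine: [hisG, hisE, hisI, hisA, hisH, hisF, hisB, hisC, hisD]
      phenylalanine: [aroG, aroB, aroD, aroE, aroK, aroA, aroC, pheA]
      tryptophan: [trpE, trpD, trpC, trpA, trpB]
  mirabilia_sim:            # eroding B-vitamin provider with split genes
    seed: 44
    genome_length: 165000
    gc_target: 0.185
    n_genes: 180
    n_split_genes: 20
    target_16s_identity: 0.96
    pathway_assignment:
      cysteine: [cysE, cysK]
      riboflavin: [ribA, ribD, ribB, ribH, ribE]
      biotin: [bioC, bioF, bioA, bioD, bioB]
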