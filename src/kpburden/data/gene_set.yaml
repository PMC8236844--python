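# Default 18-gene tryptophan-metabolism panel.
# pathway_group: protein_synthesis (TRP -> protein), serotonin (TRP -> 5-HT -> 5-HIAA),
# kynurenine (TRP -> KYN -> KYNA / QUIN -> NAD+).
# MAOA: the panel accession is NM_001270458; NM_000240 is an alternative RefSeq
# transcript seen in some reports of the same variants.
genes:
  - symbol: WARS
    aliases: [WARS1]
    transcript: NM_004184
    chromosome: chr14
    pathway_group: protein_synthesis
  - symbol: DDC
    aliases: [AADC]
    transcript: NM_001082971
    chromosome: chr7
    pathway_group: serotonin
  - symbol: MAOA
    aliases: []
    transcript: NM_001270458
    chromosome: chrX
    pathway_group: serotonin
  - symbol: TPH1
    aliases: []
    transcript: NM_004179
    chromosome: chr11
    pathway_group: serotonin
  - symbol: TPH2
    aliases: []
    transcript: NM_173353
    chromosome: chr12
    pathway_group: serotonin
  - symbol: AADAT
    aliases: [KAT2]
    transcript: NM_016228
    chromosome: chr4
    pathway_group: kynurenine
  - symbol: ACMSD
    aliases: []
    transcript: NM_138326
    chromosome: chr2
    pathway_group: kynurenine
  - symbol: AFMID
    aliases: []
    transcript: NM_001010982
    chromosome: chr17
    pathway_group: kynurenine
  - symbol: GOT2
    aliases: []
    transcript: NM_002080
    chromosome: chr16
    pathway_group: kynurenine
  - symbol: HAAO
    aliases: []
    transcript: NM_012205
    chromosome: chr2
    pathway_group: kynurenine
  - symbol: IDO1
    aliases: [INDO]
    transcript: NM_002164
    chromosome: chr8
    pathway_group: kynurenine
  - symbol: IDO2
    aliases: [INDOL1]
    transcript: NM_194294
    chromosome: chr8
    pathway_group: kynurenine
  - symbol: KMO
    aliases: []
    transcript: NM_003679
    chromosome: chr1
    pathway_group: kynurenine
  - symbol: KYAT1
    aliases: [CCBL1]
    transcript: NM_001122671
    chromosome: chr9
    pathway_group: kynurenine
  - symbol: KYAT3
    aliases: [CCBL2, KAT3]
    transcript: NM_001008662
    chromosome: chr1
    pathway_group: kynurenine
  - symbol: KYNU
    aliases: []
    transcript: NM_003937
    chromosome: chr2
    pathway_group: kynurenine
  - symbol: QPRT
    aliases: []
    transcript: NM_014298
    chromosome: chr16
    pathway_group: kynurenine
  - symbol: TDO2
    aliases: []
    transcript: NM_005651
    chromosome: chr4
    pathway_group: kynurenine
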