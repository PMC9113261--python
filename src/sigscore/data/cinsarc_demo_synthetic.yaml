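# CINSARC-style configuration.
#
# method_doi: 10.1038/nm.2174  (Chibon et al. 2010, the CINSARC signature)
#
# gene list: SYNTHETIC demo stand-in. The published signature contains 67
# genes related to mitosis and chromosome integrity; the panel below is a
# shorter list of canonical mitosis / chromosome-segregation genes assembled
# to exercise the nearest-centroid classifier, NOT the published 67-gene
# list. Replace with the published list for real analyses.
genes:
  - AURKA
  - AURKB
  - BIRC5
  - BUB1
  - BUB1B
  - CCNA2
  - CCNB1
  - CCNB2
  - CDC20
  - CDK1
  - CENPA
  - CENPE
  - CENPF
  - CHEK1
  - ESPL1
  - FOXM1
  - KIF11
  - KIF23
  - MAD2L1
  - MCM2
  - MELK
  - NDC80
  - OIP5
  - PLK1
  - PRC1
  - RRM2
  - SPAG5
  - TOP2A
  - TPX2
  - TRIP13
  - TTK
  - UBE2C
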