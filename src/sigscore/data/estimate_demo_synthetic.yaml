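# ESTIMATE-style configuration.
#
# method_doi: 10.1038/ncomms3612  (Yoshihara et al. 2013, the ESTIMATE method)
#
# purity coefficients: transcribed from the published tumor-purity calibration
#   purity = cos(a + b * ESTIMATE score)
# and valid on the monotone-decreasing cosine branch [0, pi]. Note the
# calibration was fit on Affymetrix-scale ESTIMATE scores (order 1e3-1e4).
#
# gene lists: SYNTHETIC demo stand-ins. The published method uses two
# 141-gene immune/stromal signatures; the short marker panels below are
# well-known immune-cell and stromal/ECM marker genes chosen to exercise the
# scoring machinery, NOT the published lists. Replace them with the published
# 141-gene lists for real analyses — this file is plain data and editable.
immune_genes:
  - PTPRC
  - CD2
  - CD3D
  - CD3E
  - CD3G
  - CD8A
  - GZMA
  - GZMB
  - PRF1
  - CCL5
  - CXCL9
  - CXCL10
  - IL7R
  - LCK
  - ZAP70
stroma_genes:
  - COL1A1
  - COL1A2
  - COL3A1
  - COL5A1
  - COL6A3
  - FAP
  - THY1
  - DCN
  - LUM
  - FBLN1
  - PDGFRB
  - ACTA2
  - TAGLN
  - SPARC
  - FN1
purity:
  a: 0.6049872018
  b: 0.0001467884
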