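# Immunophenoscore-style marker/weight table.
#
# method_doi: 10.1016/j.celrep.2016.12.019  (Charoentong et al. 2017)
#
# Structure follows the published procedure: four categories (MHC molecules,
# effector cells EC, suppressor cells SC, checkpoints CP); marker scores are
# averaged gene z-scores; stimulatory markers carry weight +1, inhibitory
# markers -1.
#
# Gene content: the MHC and checkpoint markers are the standard single-gene
# HUGO symbols. The EC/SC cell-type gene lists are SYNTHETIC demo stand-ins
# (small canonical marker panels), NOT the published supplementary lists —
# replace them for real analyses. This file is plain data and editable.
markers:
  - {name: B2M,       category: MHC, weight: 1,  genes: [B2M]}
  - {name: TAP1,      category: MHC, weight: 1,  genes: [TAP1]}
  - {name: TAP2,      category: MHC, weight: 1,  genes: [TAP2]}
  - {name: HLA-A,     category: MHC, weight: 1,  genes: [HLA-A]}
  - {name: HLA-B,     category: MHC, weight: 1,  genes: [HLA-B]}
  - {name: HLA-C,     category: MHC, weight: 1,  genes: [HLA-C]}
  - {name: HLA-DPA1,  category: MHC, weight: 1,  genes: [HLA-DPA1]}
  - {name: HLA-DPB1,  category: MHC, weight: 1,  genes: [HLA-DPB1]}
  - {name: HLA-E,     category: MHC, weight: 1,  genes: [HLA-E]}
  - {name: HLA-F,     category: MHC, weight: 1,  genes: [HLA-F]}
  - {name: Act_CD4,   category: EC,  weight: 1,  genes: [CD4, IL2RA, CD69, TNF]}
  - {name: Act_CD8,   category: EC,  weight: 1,  genes: [CD8A, GZMA, GZMB, PRF1, IFNG]}
  - {name: Tem_CD4,   category: EC,  weight: 1,  genes: [IL7R, CD40LG, STAT4]}
  - {name: Tem_CD8,   category: EC,  weight: 1,  genes: [EOMES, CXCR3, CCL5, KLRG1]}
  - {name: Treg,      category: SC,  weight: -1, genes: [FOXP3, IKZF2, CCR8]}
  - {name: MDSC,      category: SC,  weight: -1, genes: [CD14, ITGAM, S100A8, S100A9, ARG1]}
  - {name: PD-1,      category: CP,  weight: -1, genes: [PDCD1]}
  - {name: CTLA-4,    category: CP,  weight: -1, genes: [CTLA4]}
  - {name: LAG3,      category: CP,  weight: -1, genes: [LAG3]}
  - {name: TIGIT,     category: CP,  weight: -1, genes: [TIGIT]}
  - {name: TIM-3,     category: CP,  weight: -1, genes: [HAVCR2]}
  - {name: PD-L1,     category: CP,  weight: -1, genes: [CD274]}
  - {name: PD-L2,     category: CP,  weight: -1, genes: [PDCD1LG2]}
  - {name: IDO1,      category: CP,  weight: -1, genes: [IDO1]}
  - {name: CD27,      category: CP,  weight: 1,  genes: [CD27]}
  - {name: ICOS,      category: CP,  weight: 1,  genes: [ICOS]}
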