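# SYNTHETIC demonstration signature with up- and down-regulated gene lists,
# for exercising directional scoring (singscore) and the ssGSEA-style
# original method. Gene symbols are real EMT-associated markers; membership
# is illustrative only, not a published signature.
id: demo_updown_synthetic
keywords: [demo, emt, directional]
doi: ""
description: >
  Synthetic epithelial-mesenchymal-transition-flavoured directional set:
  mesenchymal markers up, epithelial markers down; original publication
  archetype modelled as an ssGSEA-like enrichment.
original_method: ssgsea_like
up_genes: [VIM, ZEB1, SNAI1, TWIST1, FN1]
down_genes: [CDH1, EPCAM, KRT8, KRT18]
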