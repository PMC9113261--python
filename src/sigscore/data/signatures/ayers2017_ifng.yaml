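# 6-gene interferon-gamma signature (Ayers et al. 2017, J Clin Invest).
# Original score: arithmetic mean of log-scale expression of the six genes.
id: ayers2017_ifng
keywords: [immune, ifng, interferon, tcell]
doi: 10.1172/JCI91190
description: >
  Six-gene interferon-gamma signature associated with clinical response to
  PD-1 blockade; scored in the original publication as the average of
  normalized log expression values.
original_method: mean
up_genes: [IFNG, STAT1, IDO1, CXCL10, CXCL9, HLA-DRA]
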