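# SYNTHETIC demonstration signature for the weighted-sum original method.
# The gene symbols are real proliferation markers but the coefficients are
# invented for demonstration and testing; not derived from any publication.
id: demo_weighted_synthetic
keywords: [demo, weighted, proliferation]
doi: ""
description: >
  Synthetic demonstration of a coefficient-weighted signature (weighted sum
  of fitted-model coefficients and expression values); coefficients are
  illustrative only.
original_method: weighted_sum
up_genes: [MKI67, TOP2A, CCNB1]
down_genes: [CDKN1A]
coefficients:
  MKI67: 0.45
  TOP2A: 0.30
  CCNB1: 0.25
  CDKN1A: -0.50
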