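# Cytolytic activity (CYT) signature (Rooney et al. 2015, Cell).
# The original score is the geometric mean of GZMA and PRF1 on the linear
# scale, which equals the arithmetic mean on log-scale input — the input
# contract of this package — so original_method is mean.
id: rooney2015_cyt
keywords: [immune, cytolytic, cyt]
doi: 10.1016/j.cell.2014.12.033
description: >
  Immune cytolytic activity defined by granzyme A and perforin expression;
  geometric-mean score (arithmetic mean on log-scale data).
original_method: mean
up_genes: [GZMA, PRF1]
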