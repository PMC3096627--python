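"""Gene-set over-representation on a toy DE result.

Builds a 20-gene universe with one 5-gene set, calls DE genes through the
posterior + fold-change filter, and runs the one-tailed Fisher test with
Benjamini-Hochberg adjustment.
"""

import pandas as pd

from npmvs import fold_change_filter
from npmvs.enrichment import enrich_gene_sets

results = pd.DataFrame({
    "gene_id": [f"g{i}" for i in range(20)],
    "posterior_de_prob": [0.999] * 6 + [0.10] * 14,
    "log2_fold_change": [2.1, 1.8, 1.4, -2.0, -1.6, 0.4] + [0.1] * 14,
})

up, down = fold_change_filter(results, threshold=1.0, posterior_cutoff=0.99)
print(f"up-regulated: {up}")
print(f"down-regulated: {down}")
# g5 has posterior 0.999 but |log2FC| = 0.4 < 1: excluded by the filter.

gene_sets = {"stress_response": {"g0", "g1", "g2", "g3", "g10"}}
table = enrich_gene_sets(up + down, gene_sets, universe_size=20)
print()
print(table.to_string(index=False))
# p is the exact hypergeometric upper tail P(K >= k): the chance of seeing
# at least k of the m set members among n DE draws from N genes.
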