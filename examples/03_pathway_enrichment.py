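"""Recompute a published KEGG pathway-enrichment table from its counts.

The bundled goat-ovary comparison reports, for each significant pathway, the
number of annotated DEGs (m) and annotated genes (M); with the universe
N = 22,885, n = 1,413 annotated DEGs and 242 pathways in total, the
hypergeometric p-values and BH Q-values are fully determined — and match
the published columns.
"""

import twolibde as tl
from twolibde.datasets import (GOAT_OVARY_N, GOAT_OVARY_N_DEG,
                               GOAT_OVARY_TOTAL_PATHWAYS, goat_ovary_pathways)

report = tl.pathway_report(goat_ovary_pathways(), GOAT_OVARY_N_DEG,
                           GOAT_OVARY_N, GOAT_OVARY_TOTAL_PATHWAYS)
print(tl.format_pathway_report(report))
print("p_value: P(X >= m) for X hypergeometric(N=22885, M, n=1413);")
print("q_value: BH step-up over all 242 pathways hit by a DEG.")
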