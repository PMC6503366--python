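"""Bundled worked-example data.

A published two-library RNA-seq comparison of pregnant versus nonpregnant
goat (*Capra hircus*) ovaries reported the KEGG pathways significantly
enriched among its differentially expressed genes, together with the counts
the hypergeometric test needs: 22,885 genes carried a KEGG annotation (N),
1,413 of the DEGs were annotated (n), and those DEGs hit 242 pathways in
total.  The per-pathway DEG counts (m) and annotation sizes (M) reported for
the significant pathways are reproduced here so the enrichment arithmetic
can be exercised end to end without any external download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["goat_ovary_pathways", "GOAT_OVARY_N", "GOAT_OVARY_N_DEG",
           "GOAT_OVARY_TOTAL_PATHWAYS"]

#: genes with a KEGG annotation (the hypergeometric population N)
GOAT_OVARY_N = 22885
#: DEGs carrying a KEGG annotation (the draw size n)
GOAT_OVARY_N_DEG = 1413
#: pathways hit by at least one annotated DEG (the BH test total)
GOAT_OVARY_TOTAL_PATHWAYS = 242

_ROWS = [
    ("ko04610", "Complement and coagulation cascades", 51, 235),
    ("ko05150", "Staphylococcus aureus infection", 33, 181),
    ("ko04640", "Hematopoietic cell lineage", 30, 212),
    ("ko04976", "Bile secretion", 28, 192),
    ("ko04060", "Cytokine-cytokine receptor interaction", 46, 395),
    ("ko03030", "DNA replication", 12, 51),
    ("ko05322", "Systemic lupus erythematosus", 31, 241),
    ("ko04360", "Axon guidance", 44, 403),
    ("ko05133", "Pertussis", 23, 177),
    ("ko04110", "Cell cycle", 31, 273),
    ("ko04977", "Vitamin digestion and absorption", 13, 78),
    ("ko00100", "Steroid biosynthesis", 10, 54),
]


def goat_ovary_pathways() -> pd.DataFrame:
    """Significantly enriched KEGG pathways from the goat-ovary comparison.

    Columns: pathway_id, label, m (DEGs annotated to the pathway), M (all
    genes annotated to the pathway).  Use with ``n = GOAT_OVARY_N_DEG``,
    ``N = GOAT_OVARY_N`` and a BH total of ``GOAT_OVARY_TOTAL_PATHWAYS``.
    """
    return pd.DataFrame(_ROWS, columns=["pathway_id", "label", "m", "M"])
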