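"""Relative qPCR quantification by the comparative-CT (2^-ddCt) method.

Each well contributes a Ct (threshold cycle); expression is quantified
relative to a reference gene (GAPDH by default) measured in the same runs:

    dCt(condition)  = Ct(target) - Ct(reference)        per replicate
    ddCt            = mean dCt(pregnant) - mean dCt(nonpregnant)
    relative ratio  = 2^-ddCt

Replicate-level dCt values feed a two-sample Student's t-test (Welch by
option) for the significance of the expression difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QpcrPanel", "DdctResult", "ddct_ratio", "ddct_table", "read_qpcr_tsv"]

CONDITIONS = ("nonpregnant", "pregnant")


@dataclass
class QpcrPanel:
    """Replicate Ct values for target and reference genes in two conditions.

    ``data`` columns: condition (nonpregnant/pregnant), gene_id, replicate
    (integer index pairing target and reference wells of one run), ct.
    """

    data: pd.DataFrame
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        required = {"condition", "gene_id", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table lacks columns: {sorted(missing)}")
        bad = set(self.data["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition(s): {sorted(bad)}")
        for cond in CONDITIONS:
            ref = self.data[(self.data["condition"] == cond)
                            & (self.data["gene_id"] == self.reference_gene)]
            if len(ref) < 2:
                raise ValueError(
                    f"reference gene {self.reference_gene!r} needs >= 2 "
                    f"replicates in condition {cond!r}")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene_id"]) - {self.reference_gene})

    def delta_ct(self, gene: str, condition: str) -> np.ndarray:
        """Per-replicate dCt = Ct(gene) - Ct(reference), paired by replicate."""
        sub = self.data[self.data["condition"] == condition]
        tgt = sub[sub["gene_id"] == gene].set_index("replicate")["ct"]
        ref = sub[sub["gene_id"] == self.reference_gene].set_index("replicate")["ct"]
        common = tgt.index.intersection(ref.index)
        if len(common) < 2:
            raise ValueError(
                f"gene {gene!r} needs >= 2 paired replicates in {condition!r}")
        return (tgt.loc[common] - ref.loc[common]).to_numpy(dtype=float)


@dataclass
class DdctResult:
    gene_id: str
    ratio: float
    log2_ratio: float
    replicate_ratios: np.ndarray = field(repr=False)
    p_value: float
    significant: bool


def ddct_ratio(panel: QpcrPanel, gene: str, equal_var: bool = True,
               alpha: float = 0.05) -> DdctResult:
    """Relative expression of ``gene`` (pregnant over nonpregnant).

    The ratio is 2^-ddCt from condition-mean dCt values; ``replicate_ratios``
    expresses each pregnant replicate against the mean nonpregnant dCt.  The
    p-value is a two-sample t-test on replicate dCt values (Student's by
    default, Welch with ``equal_var=False``).
    """
    if gene == panel.reference_gene:
        raise ValueError("target gene must differ from the reference gene")
    dct_n = panel.delta_ct(gene, "nonpregnant")
    dct_p = panel.delta_ct(gene, "pregnant")
    ddct = dct_p.mean() - dct_n.mean()
    ratio = float(2.0 ** (-ddct))
    rep_ratios = 2.0 ** (-(dct_p - dct_n.mean()))
    if np.var(dct_p) == 0.0 and np.var(dct_n) == 0.0:
        # degenerate noise-free input: the t statistic is 0/0 or inf
        p = 1.0 if np.isclose(ddct, 0.0) else 0.0
    else:
        p = float(stats.ttest_ind(dct_p, dct_n, equal_var=equal_var).pvalue)
    return DdctResult(gene_id=gene, ratio=ratio, log2_ratio=float(-ddct),
                      replicate_ratios=rep_ratios, p_value=p,
                      significant=bool(p < alpha))


def ddct_table(panel: QpcrPanel, equal_var: bool = True,
               alpha: float = 0.05) -> pd.DataFrame:
    """2^-ddCt summary for every target gene in the panel."""
    rows = [ddct_ratio(panel, g, equal_var=equal_var, alpha=alpha)
            for g in panel.genes]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "ratio": [r.ratio for r in rows],
            "log2_ratio": [r.log2_ratio for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
        }
    )


def read_qpcr_tsv(path: Union[str, Path], reference_gene: str = "GAPDH") -> QpcrPanel:
    """Read a (condition, gene_id, replicate, ct) TSV into a panel."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return QpcrPanel(df, reference_gene=reference_gene)
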