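"""Hypergeometric over-representation of GO terms and KEGG pathways.

Given a universe of ``N`` annotated genes of which ``n`` are differentially
expressed, a term annotated to ``M`` genes of which ``m`` are DEGs is scored
with the upper hypergeometric tail

    p = P(X >= m) = 1 - sum_{i<m} C(M,i) C(N-M, n-i) / C(N,n).

Multiple testing is handled with Bonferroni (the GO convention here) or
Benjamini-Hochberg Q-values (the KEGG convention), where the BH total may
count pathways beyond those reported (e.g. every pathway hit by at least one
DEG).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ac import bh_adjust

__all__ = [
    "AnnotationSet",
    "hypergeom_upper_p",
    "enrich",
    "kegg_qvalues",
    "read_annotation_tsv",
    "read_gmt",
]


class AnnotationSet:
    """Gene -> term mapping with an annotation universe.

    The universe is the set of genes carrying at least one annotation; it is
    the ``N`` of the enrichment test.  Term labels are optional display
    strings (pathway names, GO descriptions).
    """

    def __init__(self, gene_to_terms: Mapping[str, Iterable[str]],
                 term_labels: Mapping[str, str] | None = None):
        self.gene_to_terms = {g: frozenset(ts) for g, ts in gene_to_terms.items()
                              if len(tuple(ts)) > 0}
        self.term_labels = dict(term_labels or {})
        members: dict[str, set[str]] = {}
        for g, ts in self.gene_to_terms.items():
            for t in ts:
                members.setdefault(t, set()).add(g)
        self.term_to_genes = {t: frozenset(gs) for t, gs in members.items()}

    @property
    def universe(self) -> frozenset:
        return frozenset(self.gene_to_terms)

    @property
    def n_terms(self) -> int:
        return len(self.term_to_genes)

    def term_size(self, term: str) -> int:
        return len(self.term_to_genes.get(term, ()))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   term_labels: Mapping[str, str] | None = None) -> "AnnotationSet":
        g2t: dict[str, set[str]] = {}
        for gene, term in pairs:
            g2t.setdefault(gene, set()).add(term)
        return cls(g2t, term_labels)

    def to_pairs(self) -> list[tuple[str, str]]:
        return sorted((g, t) for g, ts in self.gene_to_terms.items() for t in ts)


def read_annotation_tsv(path: Union[str, Path]) -> AnnotationSet:
    """Two-column TSV (gene_id, term_id), '#' comments allowed."""
    pairs = []
    with Path(path).open("rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((fields[0], fields[1]))
    return AnnotationSet.from_pairs(pairs)


def read_gmt(path: Union[str, Path]) -> AnnotationSet:
    """GMT format: one term per line — term_id, description, member genes."""
    g2t: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    with Path(path).open("rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc, genes = fields[0], fields[1], fields[2:]
            labels[term] = desc
            for g in genes:
                if g:
                    g2t.setdefault(g, set()).add(term)
    return AnnotationSet(g2t, labels)


def hypergeom_upper_p(m: int, big_m: int, n: int, big_n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    Population ``big_n`` (N, annotated genes), ``big_m`` successes (M, genes
    in the term), ``n`` draws (annotated DEGs), ``m`` observed successes.
    The survival function sums the smaller tail directly, so values as small
    as 1e-15 retain full precision.
    """
    for name, v in (("m", m), ("M", big_m), ("n", n), ("N", big_n)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if big_m > big_n or n > big_n:
        raise ValueError("M and n must not exceed N")
    if m > min(n, big_m):
        raise ValueError("m must not exceed min(n, M)")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, big_n, big_m, n))


def enrich(deg_genes: Iterable[str], annotations: AnnotationSet,
           correction: str = "bonferroni", alpha: float = 0.05,
           m_total: int | None = None) -> pd.DataFrame:
    """Score every term hit by at least one DEG.

    ``deg_genes`` outside the annotation universe are dropped (they carry no
    annotation and cannot contribute to any term).  ``N`` is the universe
    size and ``n`` the number of annotated DEGs; both are recomputed from the
    annotation set.  Terms with m = 0 are excluded from testing and from the
    Bonferroni factor.  For BH, ``m_total`` optionally sets the total test
    count (>= number of tested terms).

    Returns a DataFrame sorted by (p_raw, term_id) with columns term_id,
    label, N, n, M, m, p_raw, p_corrected, significant.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    universe = annotations.universe
    if not universe:
        raise ValueError("annotation universe is empty")
    degs = set(deg_genes) & universe
    big_n, n = len(universe), len(degs)

    rows = []
    for term, members in annotations.term_to_genes.items():
        m = len(members & degs)
        if m == 0:
            continue
        big_m = len(members)
        rows.append((term, annotations.term_labels.get(term, term),
                     big_n, n, big_m, m,
                     hypergeom_upper_p(m, big_m, n, big_n)))
    df = pd.DataFrame(rows, columns=["term_id", "label", "N", "n", "M", "m",
                                     "p_raw"])
    df = df.sort_values(["p_raw", "term_id"]).reset_index(drop=True)
    t = len(df)
    if t == 0:
        df["p_corrected"] = np.empty(0, dtype=float)
        df["significant"] = np.empty(0, dtype=bool)
        return df
    if correction == "bonferroni":
        df["p_corrected"] = np.minimum(df["p_raw"] * t, 1.0)
    else:
        df["p_corrected"] = bh_adjust(df["p_raw"].to_numpy(), m_total=m_total)
    df["significant"] = df["p_corrected"] <= alpha
    return df


def kegg_qvalues(p_raw, total_pathways: int) -> np.ndarray:
    """BH Q-values over pathway p-values with an explicit pathway total.

    ``total_pathways`` counts every pathway with at least one annotated DEG,
    including those not present in ``p_raw`` (the convention behind reported
    Q-values computed from a shortlist of significant pathways).
    """
    return bh_adjust(p_raw, m_total=total_pathways)
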