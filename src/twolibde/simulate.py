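"""Synthetic two-library RNA-seq data with known ground truth.

The generator emulates the design of a pooled-ovary sequencing experiment:
one library per condition (nonpregnant = A, pregnant = B), ~13.5-13.7 million
mapped reads each, ~20,000 expressed genes, a fraction of genes truly
differentially expressed with log-normal abundance and a fraction expressed
in only one library.  Counts are negative binomial (gamma-Poisson) with a
single dispersion knob standing in for the biological variance of the pooled
animals; dispersion 0 gives pure Poisson sampling, the regime the
Audic-Claverie test assumes.

Also provided: annotation sets with planted enriched terms, and qPCR Ct
panels constructed so the expected 2^-ddCt recovers a requested true ratio.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .expression import CountTable
from .qpcr import QpcrPanel

__all__ = ["SimulationConfig", "generate_counts", "generate_annotations",
           "generate_qpcr_panel"]

LABELS = ("null", "up", "down", "specific_a", "specific_b")


class SimulationConfig(BaseModel):
    """Parameters of the two-library count simulation.

    Defaults mirror the goat-ovary study design: 20,651 expressed genes,
    library depths of 13,549,560 (nonpregnant, A) and 13,676,394 (pregnant,
    B) mapped reads, ~8.3% of genes differentially expressed (60% of them
    up in the pregnant library), and 7.1% / 9.7% of genes detected only in
    the nonpregnant / pregnant library.
    """

    n_genes: int = Field(default=20651, gt=0)
    lib_size_a: int = Field(default=13_549_560, gt=0)
    lib_size_b: int = Field(default=13_676_394, gt=0)
    frac_de: float = Field(default=0.083, ge=0.0, le=1.0)
    lfc_mean: float = Field(default=2.0, description="mean of true |log2 FC|")
    lfc_sd: float = Field(default=0.5, ge=0.0)
    frac_up: float = Field(default=0.6, ge=0.0, le=1.0)
    dispersion: float = Field(default=0.05, ge=0.0,
                              description="NB dispersion; 0 = Poisson")
    frac_specific_a: float = Field(default=0.071, ge=0.0, le=1.0)
    frac_specific_b: float = Field(default=0.097, ge=0.0, le=1.0)
    gene_length_range: tuple[int, int] = (200, 10000)
    log_expr_sd: float = Field(default=1.5, gt=0.0,
                               description="sd of log-normal abundance")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.frac_de + self.frac_specific_a + self.frac_specific_b > 1.0:
            raise ValueError(
                "frac_de + frac_specific_a + frac_specific_b must be <= 1")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be 0 < min <= max")
        return self


def _assign_labels(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_genes
    n_spec_a = round(cfg.frac_specific_a * n)
    n_spec_b = round(cfg.frac_specific_b * n)
    n_de = round(cfg.frac_de * n)
    n_up = round(cfg.frac_up * n_de)
    labels = np.array(
        ["specific_a"] * n_spec_a + ["specific_b"] * n_spec_b
        + ["up"] * n_up + ["down"] * (n_de - n_up)
        + ["null"] * (n - n_spec_a - n_spec_b - n_de),
        dtype=object,
    )
    return labels[rng.permutation(n)]


def generate_counts(config: SimulationConfig) -> tuple[CountTable, pd.DataFrame]:
    """Simulate a two-library count table and its ground truth.

    Per-gene abundance is log-normal, scaled within each library so the
    expected column total equals the configured library size.  ``up`` genes
    have higher expression in library B (pregnant); the true log2 fold
    change is split symmetrically between the two libraries.  Genes labelled
    ``specific_a``/``specific_b`` have expected expression zero in the other
    library; if sampling yields zero reads in their own library the count is
    raised to 1 so the label always matches the zero pattern.

    Returns ``(CountTable, GroundTruth)`` where GroundTruth is a DataFrame
    with columns gene_id, label, true_lfc, true_mean.  Identical seeds give
    identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_id = np.array([f"G{i:06d}" for i in range(n)], dtype=object)
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    base = rng.lognormal(mean=0.0, sigma=cfg.log_expr_sd, size=n)
    labels = _assign_labels(cfg, rng)

    true_lfc = np.zeros(n)
    de = (labels == "up") | (labels == "down")
    mags = np.abs(rng.normal(cfg.lfc_mean, cfg.lfc_sd, size=int(de.sum())))
    signs = np.where(labels[de] == "up", 1.0, -1.0)
    true_lfc[de] = signs * mags

    # per-library expression; read rate is expression * length
    expr_a = base * 2.0 ** (-true_lfc / 2.0)
    expr_b = base * 2.0 ** (true_lfc / 2.0)
    expr_a[labels == "specific_b"] = 0.0
    expr_b[labels == "specific_a"] = 0.0
    rate_a = expr_a * lengths
    rate_b = expr_b * lengths
    mu_a = cfg.lib_size_a * rate_a / rate_a.sum()
    mu_b = cfg.lib_size_b * rate_b / rate_b.sum()

    def draw(mu: np.ndarray) -> np.ndarray:
        if cfg.dispersion == 0.0:
            return rng.poisson(mu)
        shape = 1.0 / cfg.dispersion
        lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=n) * mu / shape, 0.0)
        return rng.poisson(lam)

    count_a = draw(mu_a)
    count_b = draw(mu_b)
    spec_a = labels == "specific_a"
    spec_b = labels == "specific_b"
    count_a[spec_a & (count_a == 0)] = 1
    count_b[spec_b & (count_b == 0)] = 1
    count_b[spec_a] = 0
    count_a[spec_b] = 0

    table = CountTable(gene_id, lengths, count_a, count_b)
    truth = pd.DataFrame(
        {"gene_id": gene_id, "label": labels, "true_lfc": true_lfc,
         "true_mean": base}
    )
    return table, truth


def generate_annotations(truth: pd.DataFrame, n_terms: int,
                         enriched_terms: int, enrichment_strength: float,
                         seed: int,
                         term_size_range: tuple[int, int] = (10, 100)):
    """Annotation set with ``enriched_terms`` planted DE-enriched terms.

    Members of a planted term are drawn from the truly differentially
    expressed genes (labels up/down) with probability
    ``enrichment_strength`` and uniformly from all genes otherwise; the
    remaining terms draw uniformly.  Returns ``(AnnotationSet,
    planted_term_ids)``; term ids are shuffled so planted terms are not
    identifiable by name.
    """
    from .enrichment import AnnotationSet

    if not 0 <= enriched_terms <= n_terms:
        raise ValueError("need 0 <= enriched_terms <= n_terms")
    if not 0.0 <= enrichment_strength <= 1.0:
        raise ValueError("enrichment_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth["gene_id"].to_numpy()
    de_genes = truth.loc[truth["label"].isin(["up", "down"]), "gene_id"].to_numpy()
    if enriched_terms > 0 and enrichment_strength > 0 and len(de_genes) == 0:
        raise ValueError("cannot plant enriched terms: no DE genes in truth")

    term_ids = np.array([f"T{i:04d}" for i in range(n_terms)], dtype=object)
    term_ids = term_ids[rng.permutation(n_terms)]
    planted = list(term_ids[:enriched_terms])
    lo, hi = term_size_range
    pairs: list[tuple[str, str]] = []
    for k, term in enumerate(term_ids):
        size = int(rng.integers(lo, hi + 1))
        if k < enriched_terms:
            take_de = rng.random(size) < enrichment_strength
            n_de = min(int(take_de.sum()), len(de_genes))
            members = set(rng.choice(de_genes, size=n_de, replace=False))
            pool = np.setdiff1d(genes, np.array(sorted(members), dtype=object))
            extra = rng.choice(pool, size=size - len(members), replace=False)
            members.update(extra)
        else:
            members = set(rng.choice(genes, size=min(size, len(genes)),
                                     replace=False))
        pairs.extend((g, term) for g in sorted(members))
    return AnnotationSet.from_pairs(pairs), sorted(planted)


def generate_qpcr_panel(true_ratios: Sequence[float] | dict[str, float],
                        ct_noise_sd: float = 0.2, replicates: int = 3,
                        seed: int = 0, reference_gene: str = "GAPDH",
                        base_target_ct: float = 26.0,
                        base_reference_ct: float = 18.0) -> QpcrPanel:
    """Ct panel whose noise-free 2^-ddCt equals each requested true ratio.

    ``true_ratios`` maps gene ids to pregnant/nonpregnant expression ratios
    (a bare sequence gets ids Q0001, Q0002, ...).  The pregnant-condition
    target Ct is shifted by -log2(ratio); Gaussian noise of sd
    ``ct_noise_sd`` cycles is added independently to every well.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be nonnegative")
    if not isinstance(true_ratios, dict):
        true_ratios = {f"Q{i + 1:04d}": r for i, r in enumerate(true_ratios)}
    if any(r <= 0 for r in true_ratios.values()):
        raise ValueError("true ratios must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in ("nonpregnant", "pregnant"):
        for rep in range(replicates):
            rows.append((cond, reference_gene, rep,
                         base_reference_ct + rng.normal(0, ct_noise_sd)))
    for gene, ratio in true_ratios.items():
        shift = float(np.log2(ratio))
        for cond in ("nonpregnant", "pregnant"):
            mean_ct = base_target_ct - (shift if cond == "pregnant" else 0.0)
            for rep in range(replicates):
                rows.append((cond, gene, rep,
                             mean_ct + rng.normal(0, ct_noise_sd)))
    df = pd.DataFrame(rows, columns=["condition", "gene_id", "replicate", "ct"])
    return QpcrPanel(df, reference_gene=reference_gene)
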