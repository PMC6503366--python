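"""Orchestration: simulate -> quantify -> test -> enrich -> report.

Every stage is a pure function of its declared inputs, so a fixed config and
seed reproduce byte-identical outputs.  The pipeline writes one TSV per
stage plus a JSON summary with the headline counts (genes tested, DEGs up
and down, library-specific genes, significant terms).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import ac, enrichment, expression, qpcr, simulate

__all__ = ["PipelineConfig", "run_pipeline", "pathway_report",
           "format_pathway_report"]

log = logging.getLogger("twolibde")


class PipelineConfig(BaseModel):
    """Inputs, thresholds and output location of one pipeline run.

    Exactly one of ``counts_path`` and ``simulation`` must be set; the
    annotation and qPCR inputs are optional stages.
    """

    counts_path: Optional[str] = None
    annotations_path: Optional[str] = None
    annotations_format: str = "tsv"  # "tsv" | "gmt"
    qpcr_path: Optional[str] = None
    out_dir: str = "twolibde_out"
    fdr_threshold: float = Field(default=0.001, gt=0)
    lfc_threshold: float = Field(default=1.0, gt=0)
    enrichment_alpha: float = Field(default=0.05, gt=0)
    enrichment_correction: str = "bh"  # "bonferroni" | "bh"
    min_specific_count: int = Field(default=1, ge=1)
    simulation: Optional[simulate.SimulationConfig] = None
    seed: int = 0
    log_level: str = "INFO"


def _load_counts(cfg: PipelineConfig):
    if (cfg.counts_path is None) == (cfg.simulation is None):
        raise ValueError("set exactly one of counts_path and simulation")
    if cfg.counts_path is not None:
        table = expression.read_count_table(cfg.counts_path)
        return table, None
    sim = cfg.simulation.model_copy(update={"seed": cfg.simulation.seed or cfg.seed})
    return simulate.generate_counts(sim)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the summary dict it also writes."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, truth = _load_counts(config)
    log.info("counts: %d genes, totals %d / %d", len(table),
             table.lib_total_a, table.lib_total_b)
    if truth is not None:
        expression.write_count_table(out / "counts.tsv", table)
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False,
                     float_format="%.6g")

    expr = expression.expression_table(table)
    expression.write_expression(out / "expression.tsv", expr)

    de = ac.de_table(table, fdr_threshold=config.fdr_threshold,
                     lfc_threshold=config.lfc_threshold,
                     min_count=config.min_specific_count)
    de.to_csv(out / "de_results.tsv", sep="\t", index=False,
              float_format="%.6g")
    n_up = int((de["call"] == "up").sum())
    n_down = int((de["call"] == "down").sum())
    log.info("tested %d genes: %d up, %d down", len(de), n_up, n_down)

    summary = {
        "genes_total": len(table),
        "genes_tested": len(de),
        "degs_total": n_up + n_down,
        "degs_up": n_up,
        "degs_down": n_down,
        "specific_nonpregnant": int((de["specific"] == "nonpregnant_only").sum()),
        "specific_pregnant": int((de["specific"] == "pregnant_only").sum()),
    }

    if config.annotations_path is not None:
        reader = (enrichment.read_gmt if config.annotations_format == "gmt"
                  else enrichment.read_annotation_tsv)
        ann = reader(config.annotations_path)
        degs = de.loc[de["call"] != "not_significant", "gene_id"]
        enr = enrichment.enrich(degs, ann,
                                correction=config.enrichment_correction,
                                alpha=config.enrichment_alpha)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        summary["terms_tested"] = len(enr)
        summary["terms_significant"] = int(enr["significant"].sum())
        log.info("enrichment: %d terms tested, %d significant",
                 len(enr), summary["terms_significant"])

    if config.qpcr_path is not None:
        panel = qpcr.read_qpcr_tsv(config.qpcr_path)
        qdf = qpcr.ddct_table(panel)
        qdf.to_csv(out / "qpcr.tsv", sep="\t", index=False,
                   float_format="%.6g")
        summary["qpcr_genes"] = len(qdf)
        summary["qpcr_significant"] = int(qdf["significant"].sum())

    with (out / "summary.json").open("wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def pathway_report(counts: pd.DataFrame, n_deg: int, n_universe: int,
                   total_pathways: int) -> pd.DataFrame:
    """Recompute a pathway-enrichment report from published-style counts.

    ``counts`` needs columns (pathway_id, label, m, M); ``n_deg`` is the
    number of annotated DEGs (n), ``n_universe`` the annotated-genome size
    (N), ``total_pathways`` the BH test total.  Output mirrors the layout of
    a published pathway table: percentages of n and N, raw hypergeometric p,
    and the BH Q-value, sorted by p then pathway_id.
    """
    for col in ("pathway_id", "label", "m", "M"):
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    df = counts.copy()
    df["p_value"] = [
        enrichment.hypergeom_upper_p(int(m), int(M), n_deg, n_universe)
        for m, M in zip(df["m"], df["M"])
    ]
    df = df.sort_values(["p_value", "pathway_id"]).reset_index(drop=True)
    df["q_value"] = enrichment.kegg_qvalues(df["p_value"].to_numpy(),
                                            total_pathways)
    df["m_pct_of_n"] = np.round(100.0 * df["m"] / n_deg, 2)
    df["M_pct_of_N"] = np.round(100.0 * df["M"] / n_universe, 2)
    return df[["label", "m", "m_pct_of_n", "M", "M_pct_of_N",
               "p_value", "q_value", "pathway_id"]]


def format_pathway_report(report: pd.DataFrame) -> str:
    """TSV rendering with 3-significant-digit scientific p and Q columns."""
    out = report.copy()
    out["p_value"] = out["p_value"].map(lambda v: f"{v:.2E}")
    out["q_value"] = out["q_value"].map(lambda v: f"{v:.2E}")
    out["m_pct_of_n"] = out["m_pct_of_n"].map(lambda v: f"{v:.2f}")
    out["M_pct_of_N"] = out["M_pct_of_N"].map(lambda v: f"{v:.2f}")
    return out.to_csv(sep="\t", index=False)
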