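"""Audic-Claverie exact test for two unreplicated count libraries.

For a gene with ``x`` reads in library 1 (total ``N1`` reads) and ``y`` reads
in library 2 (total ``N2``), the probability of observing ``y`` given ``x``
under equal per-read expression is

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is the posterior predictive of a Poisson rate under a flat prior — a
negative binomial in ``y`` with ``x+1`` successes and success probability
``N1/(N1+N2)``.  The two-sided p-value doubles the smaller tail of this
distribution:

    S = sum_{i=0..y} p(i|x)
    p = 2*S          if S <= 0.5
    p = 2*(1 - S)    otherwise

Everything is evaluated in log space (log-gamma), with the upper tail summed
directly when ``S > 0.5`` so that p-values far below machine epsilon relative
to 1 (e.g. 1e-300) keep full relative precision.

Also provided: Benjamini-Hochberg step-up adjustment with an explicit total
test count, DEG calling at FDR and |log2 ratio| thresholds, and detection of
library-specific (one-library-only) genes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "ac_point_prob",
    "ac_pvalue",
    "ac_pvalues",
    "bh_adjust",
    "call_degs",
    "detect_specific",
]

_TINY = 5e-324  # smallest positive subnormal; p-values are clamped into (0, 1]


def _check_inputs(x: int, y: int, n1: int, n2: int) -> None:
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def _log_point_prob(y, x: int, logr: float, log1pr: float):
    """log p(y|x); ``y`` may be an integer array."""
    y = np.asarray(y, dtype=float)
    return (
        y * logr
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * log1pr
    )


def ac_point_prob(y: int, x: int, n1: int, n2: int) -> float:
    """Point probability p(y|x) for library totals ``n1`` (x) and ``n2`` (y)."""
    _check_inputs(x, y, n1, n2)
    r = n2 / n1
    return float(np.exp(_log_point_prob(y, x, math.log(r), math.log1p(r))))


def _log_upper_tail(x: int, y: int, logr: float, log1pr: float) -> float:
    """log P(Y >= y+1 | x), summed term by term from i = y+1 upward.

    Terms eventually decay geometrically with ratio -> r/(1+r) < 1; summation
    stops once the geometric bound on the remainder is below 1e-17 of the
    accumulated mass.
    """
    i0 = y + 1
    total = -np.inf
    chunk = max(256, int(4.0 * math.sqrt(x + y + 1)))
    while True:
        idx = np.arange(i0, i0 + chunk, dtype=float)
        lp = _log_point_prob(idx, x, logr, log1pr)
        total = np.logaddexp(total, logsumexp(lp))
        last = i0 + chunk - 1
        # ratio of the next term to the last computed one
        rho = math.exp(logr - log1pr) * (x + last + 1) / (last + 1)
        if rho < 1.0:
            remainder = lp[-1] + math.log(rho) - math.log1p(-rho)
            if remainder < total + math.log(1e-17):
                return float(total)
        i0 += chunk


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value, in (0, 1].

    ``x``/``n1`` refer to one library (nonpregnant, by package convention)
    and ``y``/``n2`` to the other.  The boundary S = 0.5 falls in the 2*S
    branch, so ``ac_pvalue(0, 0, n, n) == 1.0`` exactly.
    """
    _check_inputs(x, y, n1, n2)
    r = n2 / n1
    logr, log1pr = math.log(r), math.log1p(r)
    log_lower = float(logsumexp(_log_point_prob(np.arange(y + 1), x, logr, log1pr)))
    s = math.exp(log_lower)
    if s <= 0.5:
        p = 2.0 * s
    else:
        p = 2.0 * math.exp(_log_upper_tail(x, y, logr, log1pr))
    return min(max(p, _TINY), 1.0)


def ac_pvalues(x, y, n1: int, n2: int) -> np.ndarray:
    """Vectorised :func:`ac_pvalue` over per-gene count arrays."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    return np.array([ac_pvalue(int(xi), int(yi), n1, n2) for xi, yi in zip(x, y)])


def bh_adjust(pvalues, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m_total`` is the total number of tests, which may exceed the number of
    p-values supplied (e.g. Q-values computed over the 12 reported pathways
    out of 242 tested).  Defaults to ``len(pvalues)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError("m_total must be >= number of p-values")
    if len(p) == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    raw = p[order] * m / np.arange(1, len(p) + 1)
    adj = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def detect_specific(count_a, count_b, min_count: int = 1):
    """Classify genes expressed in exactly one library.

    Library A is the nonpregnant library and B the pregnant one, so a gene
    with ``count_b >= min_count`` and ``count_a == 0`` is ``pregnant_only``.
    Accepts scalars (returns a string) or arrays (returns an object array).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    ca = np.asarray(count_a, dtype=np.int64)
    cb = np.asarray(count_b, dtype=np.int64)
    out = np.full(ca.shape, "none", dtype=object)
    out[(ca == 0) & (cb >= min_count)] = "pregnant_only"
    out[(cb == 0) & (ca >= min_count)] = "nonpregnant_only"
    return str(out[()]) if out.ndim == 0 else out


def call_degs(log2_ratio, fdr, fdr_threshold: float = 0.001,
              lfc_threshold: float = 1.0):
    """DEG call per gene: up / down / not_significant.

    A gene is ``up`` (higher in the pregnant library) when its BH-adjusted
    p-value is at most ``fdr_threshold`` and its log2 ratio is at least
    ``lfc_threshold``; ``down`` symmetrically.  Thresholds are inclusive.
    """
    lfc = np.asarray(log2_ratio, dtype=float)
    q = np.asarray(fdr, dtype=float)
    if lfc.shape != q.shape:
        raise ValueError("log2_ratio and fdr must have the same length")
    out = np.full(lfc.shape, "not_significant", dtype=object)
    sig = q <= fdr_threshold
    out[sig & (lfc >= lfc_threshold)] = "up"
    out[sig & (lfc <= -lfc_threshold)] = "down"
    return str(out[()]) if out.ndim == 0 else out


def de_table(table, zero_floor=None, fdr_threshold: float = 0.001,
             lfc_threshold: float = 1.0, min_count: int = 1) -> pd.DataFrame:
    """Full differential-expression scan of a two-library count table.

    Genes with zero counts in both libraries are excluded from testing (their
    p-value is undefined-trivial) and do not appear in the result.  The
    Audic-Claverie test is applied to raw counts with x = count_a
    (nonpregnant) and y = count_b (pregnant); BH adjustment runs over all
    tested genes.  Rows are sorted by (fdr, -|log2_ratio|, gene_id).

    Returns columns: gene_id, count_a, count_b, rpkm_a, rpkm_b, log2_ratio,
    p_value, fdr, call, specific.
    """
    from .expression import expression_table

    expr = expression_table(table, zero_floor=zero_floor)
    tested = (table.count_a + table.count_b) > 0
    df = expr.loc[tested].reset_index(drop=True)
    df.insert(1, "count_a", table.count_a[tested])
    df.insert(2, "count_b", table.count_b[tested])
    df["p_value"] = ac_pvalues(df["count_a"], df["count_b"],
                               table.lib_total_a, table.lib_total_b)
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    df["call"] = call_degs(df["log2_ratio"], df["fdr"],
                           fdr_threshold=fdr_threshold,
                           lfc_threshold=lfc_threshold)
    df["specific"] = detect_specific(df["count_a"], df["count_b"],
                                     min_count=min_count)
    df = df.sort_values(
        ["fdr", "log2_ratio", "gene_id"],
        key=lambda c: -c.abs() if c.name == "log2_ratio" else c,
    ).reset_index(drop=True)
    return df.drop(columns=["floored"])
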