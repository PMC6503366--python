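"""Count-table I/O, RPKM quantification and log2 fold change.

The unit of analysis is a pair of unreplicated sequencing libraries: library A
(nonpregnant condition) and library B (pregnant condition).  Expression is
normalised as RPKM (reads per kilobase of transcript per million mapped
reads),

    RPKM = 1e9 * C / (N * L)

where ``C`` is the number of reads uniquely aligned to the gene, ``N`` the
total reads uniquely aligned to all genes in that library, and ``L`` the gene
length in bases.  Fold change is reported as ``log2(RPKM_B / RPKM_A)``
(pregnant over nonpregnant).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "compute_rpkm",
    "log2_fold_change",
    "expression_table",
    "read_count_table",
    "write_count_table",
    "write_expression",
]


class CountTableError(ValueError):
    """Malformed count table (parse or invariant violation)."""


class CountTable:
    """Per-gene lengths and raw counts for exactly two libraries.

    ``lib_total_a``/``lib_total_b`` are the totals of uniquely mapped reads
    (the ``N`` of the RPKM formula).  When not supplied they default to the
    column sums, which equals the mapped-read total whenever the table covers
    every gene with mapped reads.
    """

    def __init__(self, gene_id, length_bp, count_a, count_b,
                 lib_total_a=None, lib_total_b=None):
        self.gene_id = np.asarray(gene_id, dtype=object)
        self.length_bp = np.asarray(length_bp, dtype=np.int64)
        self.count_a = np.asarray(count_a, dtype=np.int64)
        self.count_b = np.asarray(count_b, dtype=np.int64)
        n = len(self.gene_id)
        if not (len(self.length_bp) == len(self.count_a) == len(self.count_b) == n):
            raise CountTableError("column lengths differ")
        if len(set(self.gene_id)) != n:
            dupes = pd.Series(self.gene_id).loc[lambda s: s.duplicated()]
            raise CountTableError(f"duplicate gene_id: {dupes.iloc[0]!r}")
        if np.any(self.length_bp <= 0):
            raise CountTableError("gene lengths must be positive")
        if np.any(self.count_a < 0) or np.any(self.count_b < 0):
            raise CountTableError("counts must be nonnegative")
        self.lib_total_a = int(self.count_a.sum()) if lib_total_a is None else int(lib_total_a)
        self.lib_total_b = int(self.count_b.sum()) if lib_total_b is None else int(lib_total_b)
        if self.lib_total_a <= 0 or self.lib_total_b <= 0:
            raise CountTableError("library totals must be positive")

    def __len__(self) -> int:
        return len(self.gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "length": self.length_bp,
                "count_a": self.count_a,
                "count_b": self.count_b,
            }
        )


def compute_rpkm(count, lib_total, length_bp):
    """RPKM = 1e9 * C / (N * L); accepts scalars or arrays.

    Algebraically identical to 1e6*C / (N*L/1e3).
    """
    count = np.asarray(count, dtype=float)
    lib_total = np.asarray(lib_total, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(lib_total <= 0):
        raise ValueError("lib_total must be positive")
    if np.any(length_bp <= 0):
        raise ValueError("length_bp must be positive")
    if np.any(count < 0):
        raise ValueError("count must be nonnegative")
    out = 1e9 * count / (lib_total * length_bp)
    return float(out) if out.ndim == 0 else out


def log2_fold_change(rpkm_pregnant, rpkm_nonpregnant, zero_floor):
    """log2 ratio of pregnant over nonpregnant RPKM with a zero floor.

    Zero RPKM (a gene seen in only one library) has no finite log ratio, so
    both arguments are floored at ``zero_floor`` before the ratio is taken.
    ``zero_floor`` may be a scalar or a per-gene array (e.g. the RPKM that a
    single read would yield).
    """
    p = np.asarray(rpkm_pregnant, dtype=float)
    n = np.asarray(rpkm_nonpregnant, dtype=float)
    floor = np.asarray(zero_floor, dtype=float)
    if np.any(floor <= 0):
        raise ValueError("zero_floor must be positive")
    if np.any(p < 0) or np.any(n < 0):
        raise ValueError("RPKM values must be nonnegative")
    out = np.log2(np.maximum(p, floor) / np.maximum(n, floor))
    return float(out) if out.ndim == 0 else out


def single_read_floor(table: CountTable) -> np.ndarray:
    """Default zero floor: the per-gene RPKM of one read in the smaller library."""
    n_min = min(table.lib_total_a, table.lib_total_b)
    return 1e9 / (n_min * table.length_bp.astype(float))


def expression_table(table: CountTable, zero_floor=None) -> pd.DataFrame:
    """Per-gene RPKM pair and log2 ratio (pregnant B over nonpregnant A).

    Returns columns gene_id, rpkm_a, rpkm_b, log2_ratio, floored (True where
    the zero floor was engaged on either side).
    """
    rpkm_a = compute_rpkm(table.count_a, table.lib_total_a, table.length_bp)
    rpkm_b = compute_rpkm(table.count_b, table.lib_total_b, table.length_bp)
    floor = single_read_floor(table) if zero_floor is None else np.broadcast_to(
        np.asarray(zero_floor, dtype=float), rpkm_a.shape)
    lfc = log2_fold_change(rpkm_b, rpkm_a, floor)
    floored = (rpkm_a < floor) | (rpkm_b < floor)
    return pd.DataFrame(
        {
            "gene_id": table.gene_id,
            "rpkm_a": rpkm_a,
            "rpkm_b": rpkm_b,
            "log2_ratio": lfc,
            "floored": floored,
        }
    )


_REQUIRED_COLS = ("gene_id", "length", "count_a", "count_b")


def read_count_table(path: Union[str, Path]) -> CountTable:
    """Read the tab-separated count-table dialect.

    Layout: optional ``#lib_total_a=<int>`` / ``#lib_total_b=<int>`` metadata
    lines, then a header ``gene_id\\tlength\\tcount_a\\tcount_b`` and one row
    per gene.  Totals default to column sums when the metadata is absent.
    """
    path = Path(path)
    meta: dict[str, int] = {}
    rows = []
    header = None
    with path.open("rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip() in ("lib_total_a", "lib_total_b"):
                        try:
                            meta[key.strip()] = int(val.strip())
                        except ValueError:
                            raise CountTableError(
                                f"{path}:{lineno}: bad metadata value {val!r}")
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header[:4]) != _REQUIRED_COLS:
                    raise CountTableError(
                        f"{path}:{lineno}: expected header {_REQUIRED_COLS}, got {header}")
                continue
            if len(fields) < 4:
                raise CountTableError(f"{path}:{lineno}: expected 4 columns")
            gid, length_s, ca_s, cb_s = fields[:4]
            try:
                length, ca, cb = int(length_s), int(ca_s), int(cb_s)
            except ValueError:
                raise CountTableError(
                    f"{path}:{lineno}: non-integer length or count in {fields[:4]}")
            if length <= 0:
                raise CountTableError(f"{path}:{lineno}: nonpositive length {length}")
            if ca < 0 or cb < 0:
                raise CountTableError(f"{path}:{lineno}: negative count")
            rows.append((gid, length, ca, cb))
    if header is None or not rows:
        raise CountTableError(f"{path}: empty count table")
    gid, length, ca, cb = zip(*rows)
    try:
        return CountTable(gid, length, ca, cb,
                          meta.get("lib_total_a"), meta.get("lib_total_b"))
    except CountTableError as exc:
        raise CountTableError(f"{path}: {exc}") from None


def write_count_table(path: Union[str, Path], table: CountTable,
                      include_totals: bool = True) -> None:
    """Write the TSV dialect of :func:`read_count_table`; round-trips exactly."""
    with Path(path).open("wt", encoding="utf-8") as fh:
        if include_totals:
            fh.write(f"#lib_total_a={table.lib_total_a}\n")
            fh.write(f"#lib_total_b={table.lib_total_b}\n")
        fh.write("gene_id\tlength\tcount_a\tcount_b\n")
        for gid, length, ca, cb in zip(table.gene_id, table.length_bp,
                                       table.count_a, table.count_b):
            fh.write(f"{gid}\t{length}\t{ca}\t{cb}\n")


def write_expression(path: Union[str, Path], records: pd.DataFrame) -> None:
    """Write the expression table: RPKM to 6 significant digits, flags as 0/1."""
    out = records.copy()
    for col in ("rpkm_a", "rpkm_b"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    out["log2_ratio"] = out["log2_ratio"].map(lambda v: f"{v:.6g}")
    out["floored"] = out["floored"].astype(int)
    out.to_csv(path, sep="\t", index=False)
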