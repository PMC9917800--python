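"""Clonotype aggregation, ranking, frequencies and V×J usage matrices.

A clonotype is the unique-read class of repertoire sequencing: the set of
reads sharing V gene, J gene and CDR3 amino-acid sequence.  Copy counts are
read counts per class; frequencies are percentages of all eligible reads
(productive reads by default); ranks order clonotypes by copy count with a
deterministic lexicographic tie-break.
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import EmptyRepertoireError
from .records import AnnotatedRead

CLONOTYPE_COLUMNS = ["rank", "v_gene", "j_gene", "cdr3_aa",
                     "copy_count", "frequency_pct"]


def eligible_reads(annotated: Iterable[AnnotatedRead],
                   include_unproductive: bool = False) -> list[AnnotatedRead]:
    """Reads that enter counting: full V+J+CDR3 extraction, productive by
    default; ``include_unproductive`` additionally admits stop-codon
    junctions (still anchor-bounded and in frame)."""
    keep = ("none", "stop_codon") if include_unproductive else ("none",)
    return [ar for ar in annotated
            if ar.fail_reason in keep and ar.cdr3_aa]


def aggregate_clonotypes(annotated: Iterable[AnnotatedRead],
                         include_unproductive: bool = False,
                         nucleotide_level: bool = False) -> pd.DataFrame:
    """Collapse annotated reads into a ranked clonotype table.

    Returns a DataFrame with columns rank, v_gene, j_gene, cdr3_aa,
    copy_count, frequency_pct (plus cdr3_nt when ``nucleotide_level`` grouping
    is requested).  Clonotype keys use gene-level names (alleles collapse).
    """
    reads = eligible_reads(annotated, include_unproductive)
    if not reads:
        raise EmptyRepertoireError("empty repertoire: no eligible reads")
    key_cols = ["v_gene", "j_gene", "cdr3_aa"]
    rows = [{
        "v_gene": ar.v_hit.gene_name, "j_gene": ar.j_hit.gene_name,
        "cdr3_aa": ar.cdr3_aa, "cdr3_nt": ar.cdr3_nt,
    } for ar in reads]
    df = pd.DataFrame(rows)
    if nucleotide_level:
        key_cols = key_cols + ["cdr3_nt"]
    table = (df.groupby(key_cols, as_index=False)
               .size().rename(columns={"size": "copy_count"}))
    return rank_clonotypes(table)


def rank_clonotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Attach frequency_pct and 1-based ranks (copy desc, then lexicographic)."""
    table = table.copy()
    total = int(table["copy_count"].sum())
    table["frequency_pct"] = 100.0 * table["copy_count"] / total
    sort_cols = ["copy_count", "v_gene", "j_gene", "cdr3_aa"]
    table = table.sort_values(
        sort_cols, ascending=[False, True, True, True], kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    ordered = [c for c in CLONOTYPE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    return table[ordered + extra]


def gene_usage(clonotypes: pd.DataFrame,
               level: Literal["V", "J", "VxJ"] = "VxJ",
               weight: Literal["reads", "clonotypes"] = "reads",
               ) -> pd.Series | pd.DataFrame:
    """Percentage gene usage at V, J or V×J resolution.

    Read-weighted by default (each read counts once, the denominator matching
    the clonotype table's); ``weight="clonotypes"`` counts each unique
    clonotype once instead.  For ``level="VxJ"`` the result is a V-by-J
    matrix whose cells sum to 100.
    """
    if clonotypes.empty:
        raise EmptyRepertoireError("empty clonotype table")
    w = (clonotypes["copy_count"].to_numpy(dtype=float)
         if weight == "reads" else np.ones(len(clonotypes)))
    pct = 100.0 * w / w.sum()
    df = clonotypes.assign(pct=pct)
    if level in ("V", "J"):
        col = "v_gene" if level == "V" else "j_gene"
        return (df.groupby(col)["pct"].sum()
                  .sort_values(ascending=False, kind="mergesort"))
    if level != "VxJ":
        raise ValueError(f"unknown usage level {level!r}")
    matrix = df.pivot_table(index="v_gene", columns="j_gene", values="pct",
                            aggfunc="sum", fill_value=0.0)
    return matrix.sort_index(axis=0).sort_index(axis=1)


def usage_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """V×J matrix in long form (v_gene, j_gene, pct), zero cells dropped."""
    long = (matrix.stack().rename("pct").reset_index())
    long.columns = ["v_gene", "j_gene", "pct"]
    return long[long["pct"] > 0].reset_index(drop=True)


def top_n(clonotypes: pd.DataFrame, n: int = 30) -> pd.DataFrame:
    """First min(n, K) clonotypes by rank (the printed top-30 table)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cols = ["rank", "v_gene", "j_gene", "cdr3_aa", "frequency_pct"]
    return (clonotypes.sort_values("rank").head(n)[cols]
            .reset_index(drop=True))


def plot_usage_3d(matrix: pd.DataFrame, path: str, title: str = "") -> None:
    """Render a V×J usage matrix as the customary 3D bar surface (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(projection="3d")
    nv, nj = matrix.shape
    xs, zs = np.meshgrid(np.arange(nv), np.arange(nj), indexing="ij")
    heights = matrix.to_numpy().ravel()
    ax.bar3d(xs.ravel(), zs.ravel(), np.zeros(nv * nj),
             0.8, 0.8, heights, shade=True)
    ax.set_xticks(np.arange(nv) + 0.4)
    ax.set_xticklabels(matrix.index, rotation=90, fontsize=6)
    ax.set_yticks(np.arange(nj) + 0.4)
    ax.set_yticklabels(matrix.columns, fontsize=6)
    ax.set_zlabel("frequency (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_clonotypes(table: pd.DataFrame, path: str) -> None:
    """Serialize a clonotype table (frequencies printed to 2 decimals)."""
    out = table.copy()
    out["frequency_pct"] = out["frequency_pct"].map(lambda x: f"{x:.2f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
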