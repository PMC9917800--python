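"""Cross-sample clonotype comparison and invariant T-cell annotation.

Builds shared-clonotype tables across tissues/groups/time points (absent
entries carry the "N.D." — not detected — sentinel), tracks single clonotypes
over time, and labels clonotypes matching invariant T-cell definitions:
mouse iNKT cells carry a canonical TRAV11(d)-TRAJ18 TRA and MAIT cells a
TRAV1-TRAJ33 TRA, so both are recognisable from V/J gene usage alone, with
the canonical CDR3 kept as an optional confirmation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TcrPipeError

#: sentinel used in text outputs for clonotypes absent from a sample
ND = "N.D."

KEY_COLS = ["v_gene", "j_gene", "cdr3_aa"]


@dataclass(frozen=True)
class RepertoireSample:
    """One sample's ranked clonotype table plus metadata."""

    sample_id: str
    clonotypes: pd.DataFrame
    tissue: str = ""
    group: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        missing = set(KEY_COLS + ["frequency_pct"]) - set(self.clonotypes.columns)
        if missing:
            raise TcrPipeError(
                f"sample {self.sample_id}: clonotype table lacks {sorted(missing)}"
            )


@dataclass(frozen=True)
class InvariantDefinition:
    """Gene-segment rule identifying an invariant clonotype family.

    Matching is a prefix test on the V gene (so "TRAV11" also matches the
    "TRAV11d" spelling) plus exact J equality; ``cdr3_aa`` is the canonical
    junction, enforced only when ``cdr3_required`` is set.
    """

    label: str
    v_gene_pattern: str
    j_gene: str
    cdr3_aa: str = ""
    cdr3_required: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise TcrPipeError("invariant definition needs a label")
        if not (self.v_gene_pattern or self.j_gene or self.cdr3_aa):
            raise TcrPipeError(
                f"invariant definition {self.label}: no matching fields set"
            )

    def matches(self, v_gene: str, j_gene: str, cdr3_aa: str) -> bool:
        if self.v_gene_pattern and not v_gene.startswith(self.v_gene_pattern):
            return False
        if self.j_gene and j_gene != self.j_gene:
            return False
        if self.cdr3_required and self.cdr3_aa and cdr3_aa != self.cdr3_aa:
            return False
        return True


def default_invariant_definitions() -> list[InvariantDefinition]:
    """The bundled mouse iNKT / MAIT definitions."""
    data = resources.files("tcrpipe.data")
    with resources.as_file(data / "invariant_defs.tsv") as path:
        return load_invariant_definitions(path)


def load_invariant_definitions(path: str | Path) -> list[InvariantDefinition]:
    defs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            defs.append(InvariantDefinition(
                label=row["label"],
                v_gene_pattern=row.get("v_gene_pattern", ""),
                j_gene=row.get("j_gene", ""),
                cdr3_aa=row.get("cdr3_aa", ""),
                cdr3_required=row.get("cdr3_required", "").lower()
                in ("1", "true", "yes"),
            ))
    return defs


def shared_clonotypes(samples: Sequence[RepertoireSample],
                      order_by: str = "max") -> pd.DataFrame:
    """Cross-tabulate clonotype frequencies over >= 2 samples.

    Rows are the union of clonotype keys; each sample contributes a
    frequency_pct column, NaN where the clonotype was not detected (rendered
    as "N.D." in text output).  Rows sort by max (or mean) frequency,
    descending, then by key, so the table is invariant to sample order up to
    column order.
    """
    if len(samples) < 2:
        raise TcrPipeError("need at least two samples to compare")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise TcrPipeError(f"duplicate sample_id in {ids}")
    frames = []
    for s in samples:
        f = s.clonotypes[KEY_COLS + ["frequency_pct"]].copy()
        f = f.rename(columns={"frequency_pct": s.sample_id})
        frames.append(f.set_index(KEY_COLS))
    table = pd.concat(frames, axis=1, join="outer")
    if order_by not in ("max", "mean"):
        raise TcrPipeError(f"order_by must be 'max' or 'mean', got {order_by!r}")
    stat = table.max(axis=1) if order_by == "max" else table.mean(axis=1)
    table = (table.assign(_order=stat)
                  .sort_index(kind="mergesort")  # key order breaks stat ties
                  .sort_values("_order", ascending=False, kind="mergesort")
                  .drop(columns="_order"))
    return table.reset_index()


def annotate_invariants(table: pd.DataFrame,
                        defs: Sequence[InvariantDefinition] | None = None,
                        ) -> pd.DataFrame:
    """Add a ``label`` column: first matching definition in list order."""
    if defs is None:
        defs = default_invariant_definitions()

    def first_label(row: pd.Series) -> str:
        for d in defs:
            if d.matches(row["v_gene"], row["j_gene"], row["cdr3_aa"]):
                return d.label
        return ""

    out = table.copy()
    out["label"] = out.apply(first_label, axis=1) if len(out) else ""
    return out


def presence_over_time(samples: Sequence[RepertoireSample],
                       key: tuple[str, str, str]) -> pd.DataFrame:
    """Frequency series of one clonotype across day-ordered samples.

    Samples must share tissue and group; result has columns (day,
    frequency_pct) with NaN for days where the clonotype was not detected.
    """
    if not samples:
        raise TcrPipeError("no samples given")
    tissues = {s.tissue for s in samples}
    groups = {s.group for s in samples}
    if len(tissues) > 1 or len(groups) > 1:
        raise TcrPipeError(
            f"samples span multiple tissues/groups: {tissues}, {groups}"
        )
    v, j, aa = key
    rows = []
    for s in sorted(samples, key=lambda s: s.day):
        hit = s.clonotypes[
            (s.clonotypes["v_gene"] == v)
            & (s.clonotypes["j_gene"] == j)
            & (s.clonotypes["cdr3_aa"] == aa)
        ]
        freq = float(hit["frequency_pct"].iloc[0]) if len(hit) else np.nan
        rows.append({"day": s.day, "frequency_pct": freq})
    return pd.DataFrame(rows)


def render_nd(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Format numeric frequency columns as strings with the N.D. sentinel."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda x: ND if pd.isna(x) else f"{x:.{decimals}f}"
            )
    return out


def write_comparison(table: pd.DataFrame, path: str | Path) -> None:
    render_nd(table).to_csv(path, sep="\t", index=False, lineterminator="\n")
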