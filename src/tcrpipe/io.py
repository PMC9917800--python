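"""Readers and writers: FASTQ/FASTA (gz-transparent) and AIRR Rearrangement TSV."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FileFormatError
from .records import AnnotatedRead, ReadRecord

#: AIRR Rearrangement columns this pipeline emits, in order
AIRR_COLUMNS = [
    "sequence_id", "sequence", "v_call", "j_call",
    "junction", "junction_aa", "productive", "duplicate_count",
    "fail_reason",
]


def _open_text(path: str | Path):
    """Open plain or gzip text transparently (sniffed from magic bytes)."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records; malformed input aborts naming the line."""
    n = 0
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                yield ReadRecord(title.split()[0], seq.upper(), qual)
        except ValueError as exc:
            raise FileFormatError(
                f"{path}: malformed FASTQ near line {4 * n + 1} "
                f"(record {n + 1}): {exc}"
            ) from exc


def read_fasta(path: str | Path) -> Iterator[ReadRecord]:
    """Stream FASTA records as ReadRecords (quality None)."""
    with _open_text(path) as fh:
        n = 0
        for title, seq in SimpleFastaParser(fh):
            n += 1
            if not seq:
                raise FileFormatError(
                    f"{path}: empty sequence for record {n} ({title!r})"
                )
            yield ReadRecord(title.split()[0], seq.upper(), None)


def read_sequences(path: str | Path) -> Iterator[ReadRecord]:
    """Dispatch FASTQ vs FASTA on the first significant character."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "":  # empty file: zero reads, not a format violation
        return iter([])
    if first == "@":
        return read_fastq(path)
    if first == ">":
        return read_fasta(path)
    raise FileFormatError(f"{path}: neither FASTQ nor FASTA (starts {first!r})")


def airr_frame(annotated: Iterable[AnnotatedRead]) -> pd.DataFrame:
    """Annotated reads as an AIRR Rearrangement table (one row per read)."""
    rows = []
    for ar in annotated:
        rows.append({
            "sequence_id": ar.read_id,
            "sequence": ar.sequence,
            "v_call": (f"{ar.v_hit.gene_name}*{ar.v_hit.allele}"
                       if ar.v_hit else ""),
            "j_call": (f"{ar.j_hit.gene_name}*{ar.j_hit.allele}"
                       if ar.j_hit else ""),
            "junction": ar.cdr3_nt,
            "junction_aa": ar.cdr3_aa,
            "productive": "T" if ar.productive else "F",
            "duplicate_count": 1,
            "fail_reason": ar.fail_reason,
        })
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_airr(annotated: Iterable[AnnotatedRead], path: str | Path) -> None:
    """Write annotated reads as an AIRR Rearrangement TSV."""
    airr_frame(annotated).to_csv(path, sep="\t", index=False,
                                 lineterminator="\n")


def read_airr(path: str | Path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV back (strings preserved, counts int)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(AIRR_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise FileFormatError(f"{path}: missing AIRR columns {sorted(missing)}")
    if "duplicate_count" in df.columns:
        df["duplicate_count"] = df["duplicate_count"].astype(int)
    return df


def airr_to_annotated_keys(df: pd.DataFrame) -> pd.DataFrame:
    """Gene-level (v_gene, j_gene, cdr3_aa, fail_reason) view of an AIRR table."""
    out = pd.DataFrame({
        "v_gene": df["v_call"].str.partition("*")[0],
        "j_gene": df["j_call"].str.partition("*")[0],
        "cdr3_aa": df["junction_aa"],
        "productive": df["productive"] == "T",
    })
    out["fail_reason"] = df.get("fail_reason", "none")
    return out


def write_fasta(records: Sequence[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.read_id}\n{rec.sequence}\n")
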