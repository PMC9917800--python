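"""V/J segment reference with conserved-anchor metadata.

A reference is a FASTA of germline V and J segment nucleotide sequences plus a
sidecar TSV ("anchor table") giving, for every segment, the 0-based offset of
the conserved anchor codon: the 2nd-CYS (IMGT position 104) for V segments and
the J-PHE/J-TRP (IMGT position 118) for J segments.  Anchors are curated facts
supplied as metadata, never inferred by motif scanning of the reference.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ReferenceDBError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: codons accepted at the V anchor (Cys) and J anchor (Phe or Trp)
V_ANCHOR_CODONS = frozenset({"TGT", "TGC"})
J_ANCHOR_CODONS = frozenset({"TTT", "TTC", "TGG"})

ANCHOR_TABLE_COLUMNS = [
    "gene_name", "allele", "segment_type", "chain",
    "anchor_codon_start", "frame_offset",
]


def split_allele(token: str) -> tuple[str, str]:
    """Split a gene token like ``TRAV12D-1*01`` into (gene_name, allele).

    The gene name is otherwise treated as an opaque, case-sensitive string;
    only a trailing ``*allele`` suffix is interpreted.
    """
    if "*" in token:
        name, _, allele = token.partition("*")
        return name, allele or "01"
    return token, "01"


@dataclass(frozen=True)
class SegmentRecord:
    """One germline V or J segment with its conserved-anchor position."""

    gene_name: str
    allele: str
    segment_type: str  # "V" | "J"
    chain: str  # "TRA" | "TRB"
    sequence: str
    anchor_codon_start: int
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.segment_type not in ("V", "J"):
            raise ReferenceDBError(
                f"{self.gene_name}: segment_type must be V or J, "
                f"got {self.segment_type!r}"
            )
        if self.chain not in ("TRA", "TRB"):
            raise ReferenceDBError(
                f"{self.gene_name}: chain must be TRA or TRB, got {self.chain!r}"
            )
        if not self.sequence or set(self.sequence) - VALID_BASES:
            raise ReferenceDBError(
                f"{self.gene_name}: sequence must be non-empty uppercase ACGT"
            )
        if not 0 <= self.anchor_codon_start <= len(self.sequence) - 3:
            raise ReferenceDBError(
                f"{self.gene_name}: anchor_codon_start {self.anchor_codon_start} "
                f"outside sequence of length {len(self.sequence)}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ReferenceDBError(
                f"{self.gene_name}: frame_offset must be 0, 1 or 2"
            )
        if (self.anchor_codon_start - self.frame_offset) % 3 != 0:
            raise ReferenceDBError(
                f"{self.gene_name}: anchor_codon_start {self.anchor_codon_start} "
                f"is off the codon grid for frame_offset {self.frame_offset}"
            )
        codon = self.anchor_codon
        if self.segment_type == "V" and codon not in V_ANCHOR_CODONS:
            aa = str(Seq(codon).translate())
            raise ReferenceDBError(
                f"{self.gene_name}: anchor codon {codon} is not Cys "
                f"(translates to {aa})"
            )
        if self.segment_type == "J" and codon not in J_ANCHOR_CODONS:
            aa = str(Seq(codon).translate())
            raise ReferenceDBError(
                f"{self.gene_name}: anchor codon {codon} is not Phe or Trp "
                f"(translates to {aa})"
            )

    @property
    def anchor_codon(self) -> str:
        return self.sequence[self.anchor_codon_start:self.anchor_codon_start + 3]

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_name, self.allele)


@dataclass
class ValidationReport:
    """Per-chain segment counts plus soft warnings / fatal findings."""

    counts: dict[tuple[str, str], int]  # (chain, segment_type) -> n
    warnings: list[str] = field(default_factory=list)
    fatal: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


class ReferenceDB:
    """Indexed collection of :class:`SegmentRecord`.

    Lookups by unknown gene name fail loudly with :class:`ReferenceDBError`.
    """

    def __init__(self, segments: Iterable[SegmentRecord]):
        self.segments: list[SegmentRecord] = list(segments)
        self._by_key: dict[tuple[str, str], SegmentRecord] = {}
        self._by_name: dict[str, list[SegmentRecord]] = {}
        self._by_slice: dict[tuple[str, str], list[SegmentRecord]] = {}
        for seg in self.segments:
            if seg.key in self._by_key:
                raise ReferenceDBError(
                    f"duplicate segment {seg.gene_name}*{seg.allele}"
                )
            self._by_key[seg.key] = seg
            self._by_name.setdefault(seg.gene_name, []).append(seg)
            self._by_slice.setdefault(
                (seg.segment_type, seg.chain), []
            ).append(seg)

    def __len__(self) -> int:
        return len(self.segments)

    def lookup(self, gene_name: str, allele: str | None = None) -> SegmentRecord:
        """Return the segment for ``gene_name`` (first allele if unspecified)."""
        if allele is not None:
            try:
                return self._by_key[(gene_name, allele)]
            except KeyError:
                raise ReferenceDBError(
                    f"unknown segment {gene_name}*{allele}"
                ) from None
        try:
            return self._by_name[gene_name][0]
        except KeyError:
            raise ReferenceDBError(f"unknown segment {gene_name}") from None

    def slice(self, segment_type: str, chain: str) -> list[SegmentRecord]:
        """All segments of one type on one chain (possibly empty)."""
        return list(self._by_slice.get((segment_type, chain), []))

    @property
    def chains(self) -> list[str]:
        return sorted({s.chain for s in self.segments})


def load_reference(segment_fasta: str | Path, anchor_table: str | Path) -> ReferenceDB:
    """Load a segment FASTA plus anchor TSV into an indexed :class:`ReferenceDB`.

    FASTA headers are pipe-delimited ``gene_name|allele|segment_type|chain``
    (an allele suffix ``*NN`` on the gene token is also understood).  Every
    FASTA entry must have a matching anchor-table row; each record is validated
    against the :class:`SegmentRecord` invariants.
    """
    anchors: dict[tuple[str, str], dict[str, str]] = {}
    with open(anchor_table, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ANCHOR_TABLE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ReferenceDBError(
                f"anchor table {anchor_table} lacks columns: {sorted(missing)}"
            )
        for row in reader:
            anchors[(row["gene_name"], row["allele"])] = row

    segments = []
    for rec in SeqIO.parse(str(segment_fasta), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 4:
            token, allele, seg_type, chain = parts
            gene_name, tok_allele = split_allele(token)
            if "*" in token:
                allele = tok_allele
        else:
            raise ReferenceDBError(
                f"FASTA header {rec.id!r} is not gene|allele|segment_type|chain"
            )
        try:
            anchor_row = anchors[(gene_name, allele)]
        except KeyError:
            raise ReferenceDBError(
                f"no anchor-table row for {gene_name}*{allele}"
            ) from None
        segments.append(
            SegmentRecord(
                gene_name=gene_name,
                allele=allele,
                segment_type=seg_type,
                chain=chain,
                sequence=str(rec.seq).upper(),
                anchor_codon_start=int(anchor_row["anchor_codon_start"]),
                frame_offset=int(anchor_row["frame_offset"]),
            )
        )
    db = ReferenceDB(segments)
    logger.info("loaded %d segments from %s", len(db), segment_fasta)
    return db


def write_reference(db: ReferenceDB, segment_fasta: str | Path,
                    anchor_table: str | Path) -> None:
    """Serialize a DB back to FASTA + anchor TSV (inverse of load_reference)."""
    with open(segment_fasta, "w") as fa:
        for seg in db.segments:
            fa.write(
                f">{seg.gene_name}|{seg.allele}|{seg.segment_type}|{seg.chain}\n"
            )
            fa.write(seg.sequence + "\n")
    with open(anchor_table, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANCHOR_TABLE_COLUMNS)
        for seg in db.segments:
            writer.writerow([
                seg.gene_name, seg.allele, seg.segment_type, seg.chain,
                seg.anchor_codon_start, seg.frame_offset,
            ])


def validate_reference(db: ReferenceDB, min_length: int = 20) -> ValidationReport:
    """Report per-chain V/J counts plus soft warnings (short segments)."""
    report = ValidationReport(counts={})
    if len(db) == 0:
        report.fatal.append("no segments loaded")
        return report
    for seg in db.segments:
        key = (seg.chain, seg.segment_type)
        report.counts[key] = report.counts.get(key, 0) + 1
        if len(seg.sequence) < min_length:
            report.warnings.append(
                f"{seg.gene_name}*{seg.allele}: length {len(seg.sequence)} nt "
                f"< minimum {min_length}"
            )
    for chain in db.chains:
        for seg_type in ("V", "J"):
            if (chain, seg_type) not in report.counts:
                report.fatal.append(f"chain {chain} has no {seg_type} segments")
    return report


def toy_reference() -> ReferenceDB:
    """Load the small bundled reference used in tests and examples.

    The bundled segments are synthetic (randomly generated bodies with valid
    Cys/Phe anchors and a Gly codon after every J anchor) but are named after
    real mouse genes, including TRAV11, TRAV12D-1, TRAV1, TRAJ18, TRAJ22 and
    TRAJ33, so invariant-T-cell clonotypes can be exercised offline.
    """
    data = resources.files("tcrpipe.data")
    with resources.as_file(data / "toy_reference.fasta") as fa, \
            resources.as_file(data / "toy_anchors.tsv") as tsv:
        return load_reference(fa, tsv)
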