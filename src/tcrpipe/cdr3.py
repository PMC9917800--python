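"""Anchor-bounded CDR3 extraction and translation.

The CDR3 junction runs from the conserved V-segment cysteine (IMGT 104) to
the conserved J-segment phenylalanine/tryptophan (IMGT 118), both inclusive;
the glycine that follows (IMGT 119) must be present in the read and is used
as a frame check but is not part of the junction.  Anchor positions are
curated reference metadata projected onto each read through its V and J
alignments — if an anchor base aligns to a gap or falls outside the aligned
block, the read fails rather than guessing a shifted anchor.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable

from Bio.Seq import Seq

from .align import (AssignmentParams, SegmentHit, assign_segment,
                    read_coordinate_of)
from .errors import TcrPipeError
from .records import AnnotatedRead, ReadRecord
from .reference import ReferenceDB

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def translate(nt: str) -> str:
    """Standard-code translation; stops rendered as ``*``."""
    if len(nt) % 3 != 0:
        raise TcrPipeError(f"length {len(nt)} is not a multiple of 3")
    if set(nt) - set("ACGT"):
        raise TcrPipeError(f"sequence contains non-ACGT bases: {nt!r}")
    return str(Seq(nt).translate())


def locate_cdr3(read: str, v_hit: SegmentHit, j_hit: SegmentHit,
                db: ReferenceDB) -> tuple[int, int] | str:
    """Project the V and J anchor codons onto the read.

    Returns 0-based half-open read coordinates (cdr3_start, cdr3_end) of the
    anchor-inclusive junction, or a failure code: ``no_anchor_c`` when the V
    anchor is unreachable, ``no_anchor_fg`` when the J anchor or following
    Gly codon is, ``out_of_frame`` when the projected span is not a whole
    number of codons.
    """
    v_seg = db.lookup(v_hit.gene_name, v_hit.allele)
    j_seg = db.lookup(j_hit.gene_name, j_hit.allele)

    cdr3_start = read_coordinate_of(v_hit, v_seg.anchor_codon_start)
    if cdr3_start is None:
        return "no_anchor_c"
    j_anchor_last = read_coordinate_of(j_hit, j_seg.anchor_codon_start + 2)
    if j_anchor_last is None:
        return "no_anchor_fg"
    cdr3_end = j_anchor_last + 1
    if cdr3_end - cdr3_start < 6 or cdr3_end > len(read):
        return "no_anchor_fg"
    if (cdr3_end - cdr3_start) % 3 != 0:
        return "out_of_frame"
    gly_codon = read[cdr3_end:cdr3_end + 3]
    if len(gly_codon) < 3 or translate(gly_codon) != "G":
        return "no_anchor_fg"
    return cdr3_start, cdr3_end


def call_productivity(ar: AnnotatedRead) -> bool:
    """A junction is productive when in-frame, stop-free and C...F/W bounded."""
    if not ar.cdr3_aa:
        return False
    return ("*" not in ar.cdr3_aa and ar.cdr3_aa[0] == "C"
            and ar.cdr3_aa[-1] in "FW")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def _annotate_vj(read: ReadRecord, db: ReferenceDB, chain: str,
                 params: AssignmentParams) -> AnnotatedRead:
    v_hit = assign_segment(read.sequence, db, "V", chain, params)
    if v_hit is None:
        return AnnotatedRead(read.read_id, read.sequence, fail_reason="no_v")
    j_hit = assign_segment(read.sequence, db, "J", chain, params)
    if j_hit is None:
        return AnnotatedRead(read.read_id, read.sequence, v_hit=v_hit,
                             fail_reason="no_j")
    if v_hit.read_end - j_hit.read_start > params.max_vj_overlap:
        return AnnotatedRead(read.read_id, read.sequence, v_hit=v_hit,
                             j_hit=j_hit, fail_reason="vj_overlap")
    return AnnotatedRead(read.read_id, read.sequence, v_hit=v_hit,
                         j_hit=j_hit, fail_reason="none")


def annotate_read(read: ReadRecord, db: ReferenceDB, chain: str = "TRA",
                  params: AssignmentParams = AssignmentParams(),
                  both_strands: bool = False) -> AnnotatedRead:
    """Assign V and J, extract the CDR3 and call productivity for one read.

    V and J are assigned independently; the read passes the V/J stage only if
    both hits exist and the V aligned block ends before the J block begins.
    With ``both_strands`` the reverse complement is also annotated and the
    orientation with the higher combined V+J score wins (amplicons normally
    have a fixed orientation, so the default scans one strand).
    """
    ar = _annotate_vj(read, db, chain, params)
    if both_strands:
        rc = ReadRecord(read.read_id, reverse_complement(read.sequence),
                        read.quality)
        ar_rc = _annotate_vj(rc, db, chain, params)
        if _vj_score(ar_rc) > _vj_score(ar):
            ar = ar_rc
    if not ar.pass_vj:
        return ar

    located = locate_cdr3(ar.sequence, ar.v_hit, ar.j_hit, db)
    if isinstance(located, str):
        return ar.with_failure(located)
    cdr3_start, cdr3_end = located
    cdr3_nt = ar.sequence[cdr3_start:cdr3_end]
    cdr3_aa = translate(cdr3_nt)
    # conserved anchors must survive in the read itself (sequencing errors
    # can destroy them even when the alignment projects cleanly)
    if cdr3_aa[0] != "C":
        return ar.with_failure("no_anchor_c")
    if cdr3_aa[-1] not in "FW":
        return ar.with_failure("no_anchor_fg")
    ar = AnnotatedRead(
        read_id=ar.read_id, sequence=ar.sequence, v_hit=ar.v_hit,
        j_hit=ar.j_hit, cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa,
        productive=False,
        fail_reason="stop_codon" if "*" in cdr3_aa else "none",
    )
    if ar.fail_reason == "none":
        ar = replace(ar, productive=call_productivity(ar))
    return ar


def _vj_score(ar: AnnotatedRead) -> int:
    score = 0
    if ar.v_hit is not None:
        score += ar.v_hit.score
    if ar.j_hit is not None:
        score += ar.j_hit.score
    if ar.fail_reason in ("no_v", "no_j", "vj_overlap") and not ar.pass_vj:
        score -= 1  # prefer an orientation that passes outright on ties
    return score


def annotate_reads(reads: Iterable[ReadRecord], db: ReferenceDB,
                   chain: str = "TRA",
                   params: AssignmentParams = AssignmentParams(),
                   both_strands: bool = False,
                   cache: bool = True) -> list[AnnotatedRead]:
    """Annotate a read stream; identical sequences share one alignment.

    Amplicon data is highly redundant (many reads per clone), so annotation
    results are memoised by sequence string when ``cache`` is on.
    """
    memo: dict[str, AnnotatedRead] = {}
    out: list[AnnotatedRead] = []
    for read in reads:
        if cache and read.sequence in memo:
            template = memo[read.sequence]
            out.append(AnnotatedRead(
                read_id=read.read_id, sequence=template.sequence,
                v_hit=template.v_hit, j_hit=template.j_hit,
                cdr3_nt=template.cdr3_nt, cdr3_aa=template.cdr3_aa,
                productive=template.productive,
                fail_reason=template.fail_reason,
            ))
            continue
        ar = annotate_read(read, db, chain, params, both_strands)
        if cache:
            memo[read.sequence] = ar
        out.append(ar)
    return out
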