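"""Lightweight read-level records shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .align import SegmentHit

#: machine-readable annotation failure reasons, in pipeline order
FAIL_REASONS = (
    "none", "no_v", "no_j", "vj_overlap",
    "no_anchor_c", "no_anchor_fg", "out_of_frame", "stop_codon",
)


@dataclass(frozen=True)
class ReadRecord:
    """One input read (FASTQ quality optional)."""

    read_id: str
    sequence: str
    quality: str | None = None


@dataclass(frozen=True)
class AnnotatedRead:
    """A read with its V/J hits and extracted CDR3.

    ``fail_reason == "none"`` guarantees a well-formed anchor-bounded junction
    (in frame, Cys...Phe/Trp); junctions containing a stop codon are retained
    with ``fail_reason == "stop_codon"`` and ``productive=False``.
    """

    read_id: str
    sequence: str
    v_hit: SegmentHit | None = None
    j_hit: SegmentHit | None = None
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    productive: bool = False
    fail_reason: str = "no_v"

    def __post_init__(self) -> None:
        if self.fail_reason not in FAIL_REASONS:
            raise ValueError(f"unknown fail_reason {self.fail_reason!r}")

    @property
    def pass_vj(self) -> bool:
        return self.v_hit is not None and self.j_hit is not None and \
            self.fail_reason not in ("no_v", "no_j", "vj_overlap")

    def with_failure(self, reason: str) -> "AnnotatedRead":
        return replace(self, fail_reason=reason, productive=False,
                       cdr3_nt="", cdr3_aa="")
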