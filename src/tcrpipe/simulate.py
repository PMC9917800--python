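"""Ground-truthed V(D)J amplicon simulator.

Emulates merged single-sequence TRA/TRB amplicons spanning V–junction–J, the
read structure produced by 5'-adaptor-ligation TCR amplicon sequencing after
pair merging.  Each simulated clone is a V gene, a J gene, exonuclease-style
trims at the V 3' end and J 5' end, and an untemplated N-insert; clone
abundances follow a strongly skewed (lognormal by default) spectrum, and known
invariant/antigen-associated clonotypes can be spiked in at fixed frequencies
by reverse-translating their CDR3 amino-acid sequences.

The simulator is the ground truth the rest of the pipeline is tested against:
every emitted read is linked to its generating clone in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .errors import SimulationError
from .reference import ReferenceDB, SegmentRecord

_BASES = np.array(list("ACGT"))

#: lexicographically smallest codon per amino acid (standard code)
_MIN_CODON = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate())
            _MIN_CODON.setdefault(_aa, _codon)


@dataclass(frozen=True)
class SimulatedClone:
    """One ground-truth clone with its junction construction parameters."""

    clone_id: str
    v_gene: str
    j_gene: str
    v_trim: int
    j_trim: int
    n_insert: str
    cdr3_nt: str  # Cys..Phe/Trp anchor-inclusive
    cdr3_aa: str
    junction_nt: str  # cdr3_nt plus the following Gly codon
    productive: bool
    true_frequency: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass
class SimulationConfig:
    """Parameters of one simulated repertoire.

    Defaults give a strongly skewed clone-size spectrum (lognormal sigma=1.5)
    with modest junctional trimming and geometric N-insert lengths; none of
    them is calibrated to a particular sequencing study.
    """

    n_clones: int = 50
    chain: str = "TRA"
    abundance_model: str = "lognormal"  # "lognormal" | "powerlaw"
    abundance_sigma: float = 1.5  # lognormal shape
    abundance_alpha: float = 1.5  # powerlaw exponent
    trim_max: int = 6
    n_insert_geometric_p: float = 0.4
    read_count: int = 10_000
    error_rate: float = 0.0
    productive_only: bool = True
    spike_ins: list[tuple[str, str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for frac, name in [
            (self.n_insert_geometric_p, "n_insert_geometric_p"),
            (self.error_rate, "error_rate"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {frac}")
        spike_total = sum(s[3] for s in self.spike_ins)
        if spike_total >= 1.0:
            raise SimulationError(
                f"spike-in frequencies sum to {spike_total}, must be < 1"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "spike_ins" in raw:
            raw["spike_ins"] = [tuple(s) for s in raw["spike_ins"]]
        return cls(**raw)


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _is_productive_junction(cdr3_nt: str) -> bool:
    if len(cdr3_nt) % 3 != 0 or len(cdr3_nt) < 9:
        return False
    aa = _translate(cdr3_nt)
    return "*" not in aa and aa[0] == "C" and aa[-1] in "FW"


def _assemble(v: SegmentRecord, j: SegmentRecord, v_trim: int, j_trim: int,
              n_insert: str) -> tuple[str, str, str] | None:
    """Return (cdr3_nt, junction_nt, amplicon) or None if an anchor is lost."""
    if v_trim > len(v.sequence) - (v.anchor_codon_start + 3):
        return None  # trim cut into the Cys codon
    if j_trim > j.anchor_codon_start:
        return None  # trim cut into the Phe/Trp codon
    if len(j.sequence) < j.anchor_codon_start + 6:
        return None  # no room for the following Gly codon
    v_part = v.sequence[: len(v.sequence) - v_trim]
    j_part = j.sequence[j_trim:]
    amplicon = v_part + n_insert + j_part
    cdr3_start = v.anchor_codon_start
    cdr3_end = (len(v_part) + len(n_insert)
                + (j.anchor_codon_start + 3 - j_trim))
    cdr3_nt = amplicon[cdr3_start:cdr3_end]
    junction_nt = amplicon[cdr3_start:cdr3_end + 3]
    return cdr3_nt, junction_nt, amplicon


def clone_amplicon(clone: SimulatedClone, db: ReferenceDB) -> str:
    """Reconstruct a clone's error-free amplicon from the reference."""
    v = db.lookup(clone.v_gene)
    j = db.lookup(clone.j_gene)
    parts = _assemble(v, j, clone.v_trim, clone.j_trim, clone.n_insert)
    if parts is None:
        raise SimulationError(f"clone {clone.clone_id} is not reconstructible")
    cdr3_nt, _, amplicon = parts
    if cdr3_nt != clone.cdr3_nt:
        raise SimulationError(
            f"clone {clone.clone_id}: junction does not reconstruct"
        )
    return amplicon


def _build_spike(clone_id: str, v_gene: str, j_gene: str, cdr3_aa: str,
                 freq: float, db: ReferenceDB) -> SimulatedClone:
    """Construct a clone carrying an exact requested CDR3.

    V contributes its Cys codon, J its anchor codon onward; interior amino
    acids are reverse-translated with the lexicographically smallest codon
    each, which keeps the construction deterministic.
    """
    v = db.lookup(v_gene)
    j = db.lookup(j_gene)
    if not cdr3_aa or cdr3_aa[0] != "C":
        raise SimulationError(
            f"spike-in CDR3 {cdr3_aa!r} does not start with the V anchor Cys"
        )
    j_anchor_aa = _translate(j.anchor_codon)
    if cdr3_aa[-1] != j_anchor_aa:
        raise SimulationError(
            f"spike-in CDR3 {cdr3_aa!r} ends {cdr3_aa[-1]!r} but {j_gene}'s "
            f"anchor codon encodes {j_anchor_aa!r}"
        )
    interior = cdr3_aa[1:-1]
    if any(aa not in _MIN_CODON or aa == "*" for aa in interior):
        raise SimulationError(f"spike-in CDR3 {cdr3_aa!r} is not translatable")
    n_insert = "".join(_MIN_CODON[aa] for aa in interior)
    v_trim = len(v.sequence) - (v.anchor_codon_start + 3)
    j_trim = j.anchor_codon_start
    parts = _assemble(v, j, v_trim, j_trim, n_insert)
    assert parts is not None
    cdr3_nt, junction_nt, _ = parts
    got = _translate(cdr3_nt)
    if got != cdr3_aa:
        raise SimulationError(
            f"spike-in construction for {cdr3_aa!r} yielded {got!r}"
        )
    return SimulatedClone(
        clone_id=clone_id, v_gene=v_gene, j_gene=j_gene,
        v_trim=v_trim, j_trim=j_trim, n_insert=n_insert,
        cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa, junction_nt=junction_nt,
        productive=True, true_frequency=freq,
    )


def _abundances(cfg: SimulationConfig, n: int, rng: np.random.Generator
                ) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if cfg.abundance_model == "lognormal":
        w = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n)
    elif cfg.abundance_model == "powerlaw":
        w = (np.arange(1, n + 1, dtype=float)) ** (-cfg.abundance_alpha)
        rng.shuffle(w)
    else:
        raise SimulationError(f"unknown abundance model {cfg.abundance_model!r}")
    return w / w.sum()


def simulate_repertoire(cfg: SimulationConfig, db: ReferenceDB,
                        ) -> list[SimulatedClone]:
    """Draw a repertoire of ``n_clones`` background clones plus spike-ins.

    Frequencies are renormalized so the repertoire sums to exactly 1; the
    same config and seed always produce the same clone table.  Background
    clones are drawn with distinct (V, J, CDR3aa) keys.
    """
    rng = np.random.default_rng(cfg.seed)
    v_segs = db.slice("V", cfg.chain)
    j_segs = db.slice("J", cfg.chain)
    if not v_segs or not j_segs:
        raise SimulationError(f"reference has no V/J segments for {cfg.chain}")

    spikes = [
        _build_spike(f"spike{i + 1}", v, j, aa, f, db)
        for i, (v, j, aa, f) in enumerate(cfg.spike_ins)
    ]
    taken = {c.key for c in spikes}

    clones: list[SimulatedClone] = []
    attempts = 0
    while len(clones) < cfg.n_clones:
        attempts += 1
        if attempts > 200 * max(cfg.n_clones, 1):
            raise SimulationError(
                "could not draw enough distinct productive clones; "
                "loosen trim/insert settings or enlarge the reference"
            )
        v = v_segs[rng.integers(len(v_segs))]
        j = j_segs[rng.integers(len(j_segs))]
        v_trim = int(rng.integers(0, cfg.trim_max + 1))
        j_trim = int(rng.integers(0, cfg.trim_max + 1))
        ins_len = int(rng.geometric(cfg.n_insert_geometric_p) - 1)
        n_insert = "".join(rng.choice(_BASES, ins_len))
        parts = _assemble(v, j, v_trim, j_trim, n_insert)
        if parts is None:
            continue
        cdr3_nt, junction_nt, _ = parts
        productive = _is_productive_junction(cdr3_nt)
        if cfg.productive_only and not productive:
            continue
        cdr3_aa = _translate(cdr3_nt) if len(cdr3_nt) % 3 == 0 else ""
        key = (v.gene_name, j.gene_name, cdr3_aa)
        if key in taken:
            continue
        taken.add(key)
        clones.append(SimulatedClone(
            clone_id=f"clone{len(clones) + 1:04d}",
            v_gene=v.gene_name, j_gene=j.gene_name,
            v_trim=v_trim, j_trim=j_trim, n_insert=n_insert,
            cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa, junction_nt=junction_nt,
            productive=productive, true_frequency=0.0,
        ))

    spike_total = sum(c.true_frequency for c in spikes)
    bg = _abundances(cfg, len(clones), rng) * (1.0 - spike_total)
    clones = [replace(c, true_frequency=float(f)) for c, f in zip(clones, bg)]
    out = spikes + clones
    total = sum(c.true_frequency for c in out)
    out = [replace(c, true_frequency=c.true_frequency / total) for c in out]
    return out


def generate_reads(clones: Sequence[SimulatedClone], cfg: SimulationConfig,
                   db: ReferenceDB) -> tuple[list[tuple[str, str, str]],
                                             pd.DataFrame]:
    """Sample ``read_count`` error-bearing reads from a clone table.

    Reads are multinomially assigned to clones by true frequency; substitution
    errors are i.i.d. per base at ``error_rate`` (no indels).  Returns 4-tuple
    FASTQ-ready records ``(read_id, sequence, quality)`` plus a truth table
    with one row per read.
    """
    if cfg.read_count <= 0:
        raise SimulationError(f"read_count must be positive, got {cfg.read_count}")
    rng = np.random.default_rng(cfg.seed + 1)
    freqs = np.array([c.true_frequency for c in clones])
    counts = rng.multinomial(cfg.read_count, freqs / freqs.sum())

    amplicons = [clone_amplicon(c, db) for c in clones]
    order = rng.permutation(cfg.read_count)
    clone_of = np.repeat(np.arange(len(clones)), counts)[order]

    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    for i, ci in enumerate(clone_of):
        clone = clones[ci]
        seq = np.frombuffer(amplicons[ci].encode(), dtype="S1").copy()
        if cfg.error_rate > 0:
            hit = rng.random(len(seq)) < cfg.error_rate
            if hit.any():
                idx = np.flatnonzero(hit)
                # substitute with one of the three other bases, uniformly
                cur = np.searchsorted(_BASES, seq[idx].astype("U1"))
                repl = (cur + rng.integers(1, 4, size=len(idx))) % 4
                seq[idx] = _BASES[repl].astype("S1")
        sequence = seq.tobytes().decode()
        read_id = f"read{i + 1:06d}"
        reads.append((read_id, sequence, "I" * len(sequence)))
        truth_rows.append((read_id, clone.clone_id, clone.v_gene,
                           clone.j_gene, clone.cdr3_aa))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "clone_id", "v_gene", "j_gene", "cdr3_aa"]
    )
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write (read_id, sequence, quality) records as a 4-line FASTQ."""
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def clone_table(clones: Sequence[SimulatedClone]) -> pd.DataFrame:
    """Clone ground truth as a DataFrame (one row per clone)."""
    return pd.DataFrame([{
        "clone_id": c.clone_id, "v_gene": c.v_gene, "j_gene": c.j_gene,
        "v_trim": c.v_trim, "j_trim": c.j_trim, "n_insert": c.n_insert,
        "cdr3_nt": c.cdr3_nt, "cdr3_aa": c.cdr3_aa,
        "junction_nt": c.junction_nt, "productive": c.productive,
        "true_frequency": c.true_frequency,
    } for c in clones])
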