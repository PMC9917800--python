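"""End-to-end pipeline: reads -> annotation -> clonotypes -> usage tables.

One call produces, in the output directory:

* ``annotated.airr.tsv`` — per-read AIRR Rearrangement table
* ``clonotypes.tsv``     — ranked clonotype table
* ``top.tsv``            — the top-N ranking
* ``v_usage.tsv`` / ``j_usage.tsv`` / ``vj_usage.tsv`` — percentage usage
* ``manifest.json``      — version, config hash, input checksum and the
  read-accounting breakdown (input = pass + per-reason failures)

Outputs are deterministic functions of (inputs, config); a failed run removes
any partial outputs it created.
"""

from __future__ import annotations

import collections
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import AssignmentParams
from .cdr3 import annotate_reads
from .clonotypes import (aggregate_clonotypes, gene_usage, top_n, usage_long,
                         write_clonotypes)
from .errors import PipelineError
from .io import read_sequences, write_airr
from .records import FAIL_REASONS
from .reference import ReferenceDB, load_reference

logger = logging.getLogger(__name__)

OUTPUT_FILES = ["annotated.airr.tsv", "clonotypes.tsv", "top.tsv",
                "v_usage.tsv", "j_usage.tsv", "vj_usage.tsv", "manifest.json"]


@dataclass
class PipelineConfig:
    reference_fasta: str = ""
    anchor_table: str = ""
    chain: str = "TRA"
    params: AssignmentParams = field(default_factory=AssignmentParams)
    include_unproductive: bool = False
    both_strands: bool = False
    top_n: int = 30
    out_dir: str = "tcrpipe_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, reads_path: str | Path,
                 db: ReferenceDB | None = None) -> dict:
    """Run annotate -> clonotype -> usage on one reads file.

    Returns the run manifest (also written as JSON).  Every input read is
    accounted for exactly once across pass/fail categories.
    """
    reads_path = Path(reads_path)
    if not reads_path.exists():
        raise PipelineError(f"reads file not found: {reads_path}")
    if db is None:
        db = load_reference(cfg.reference_fasta, cfg.anchor_table)

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        reads = list(read_sequences(reads_path))
        if not reads:
            raise PipelineError(f"no reads in {reads_path}")

        annotated = annotate_reads(
            reads, db, chain=cfg.chain, params=cfg.params,
            both_strands=cfg.both_strands,
        )
        by_reason = collections.Counter(ar.fail_reason for ar in annotated)
        n_pass = by_reason.get("none", 0)

        airr_path = out_dir / "annotated.airr.tsv"
        write_airr(annotated, airr_path)
        created.append(airr_path)

        table = aggregate_clonotypes(
            annotated, include_unproductive=cfg.include_unproductive)
        clono_path = out_dir / "clonotypes.tsv"
        write_clonotypes(table, clono_path)
        created.append(clono_path)

        top_path = out_dir / "top.tsv"
        write_clonotypes(top_n(table, cfg.top_n), top_path)
        created.append(top_path)

        for level, name in [("V", "v_usage.tsv"), ("J", "j_usage.tsv")]:
            usage = gene_usage(table, level=level)
            p = out_dir / name
            usage.rename("pct").to_frame().reset_index().to_csv(
                p, sep="\t", index=False, float_format="%.6f",
                lineterminator="\n")
            created.append(p)
        vj = gene_usage(table, level="VxJ")
        vj_path = out_dir / "vj_usage.tsv"
        usage_long(vj).to_csv(vj_path, sep="\t", index=False,
                              float_format="%.6f", lineterminator="\n")
        created.append(vj_path)

        manifest = {
            "tool": "tcrpipe",
            "version": __version__,
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "input": {"path": str(reads_path), "sha256": _sha256(reads_path)},
            "reads": {
                "n_input": len(reads),
                "n_pass": n_pass,
                "fail_by_reason": {
                    r: by_reason.get(r, 0) for r in FAIL_REASONS if r != "none"
                },
            },
            "clonotypes": int(len(table)),
        }
        accounted = n_pass + sum(manifest["reads"]["fail_by_reason"].values())
        if accounted != len(reads):
            raise PipelineError(
                f"read accounting broken: {len(reads)} in, {accounted} out"
            )
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        created.append(manifest_path)
        logger.info("pipeline done: %d reads, %d pass, %d clonotypes "
                    "(config %s)", len(reads), n_pass, len(table),
                    cfg.config_hash())
        return manifest
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise
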