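"""Independent oracles used by the test suite.

These deliberately share no code with the package: the alignment oracle is an
exhaustive Gotoh dynamic program over every reference segment (plain loops,
numba-compiled for speed), and the counting oracle is a dict-based
tally-sort.  Both recompute from first principles what the pipeline computes
through biotite/pandas.
"""

from __future__ import annotations

import collections

import numpy as np
from numba import njit

_CODE = {b: i for i, b in enumerate("ACGT")}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.int64)


@njit(cache=True)
def _sw_best_score(a, b, match, mismatch, gap_open, gap_extend):
    """Local affine-gap alignment score; a length-n gap costs
    gap_open + (n-1)*gap_extend."""
    n, m = len(a), len(b)
    neg = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


def sw_score(read: str, segment: str, match=2, mismatch=-2,
             gap_open=-4, gap_extend=-1) -> int:
    return int(_sw_best_score(encode(read), encode(segment),
                              match, mismatch, gap_open, gap_extend))


def best_segment(read: str, segments, match=2, mismatch=-2,
                 gap_open=-4, gap_extend=-1):
    """Exhaustive scan: (gene_name, score) of the best-scoring segment.

    Ties break by lexicographically smallest gene name, mirroring the
    pipeline's documented final tie-break (score/identity/span ties between
    *different* genes are vanishingly rare for the toy reference).
    """
    best_name, best_score = None, -1
    for seg in sorted(segments, key=lambda s: s.gene_name):
        sc = sw_score(read, seg.sequence, match, mismatch, gap_open, gap_extend)
        if sc > best_score:
            best_name, best_score = seg.gene_name, sc
    return best_name, best_score


def count_clonotypes(keys):
    """Tally (v, j, cdr3_aa) keys; return rows sorted like the pipeline:
    copy desc, then lexicographic key; with rank and percentage."""
    counts = collections.Counter(keys)
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        {"rank": i + 1, "v_gene": k[0], "j_gene": k[1], "cdr3_aa": k[2],
         "copy_count": c, "frequency_pct": 100.0 * c / total}
        for i, (k, c) in enumerate(rows)
    ]


def expected_cdr3_span(clone, db) -> tuple[int, int]:
    """Closed-form junction coordinates on a clean read, straight from the
    clone's construction parameters (no alignment involved)."""
    v = db.lookup(clone.v_gene)
    j = db.lookup(clone.j_gene)
    v_kept = len(v.sequence) - clone.v_trim
    start = v.anchor_codon_start
    end = v_kept + len(clone.n_insert) + (j.anchor_codon_start + 3 - clone.j_trim)
    return start, end
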