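"""Regenerates the bundled toy reference data files (run from the repo root)."""
import sys
import numpy as np

sys.path.insert(0, "src")
from tcrpipe.reference import ReferenceDB, SegmentRecord, write_reference

rng = np.random.default_rng(20230207)
BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}


def rand_nt(n):
    return "".join(rng.choice(BASES, n))


def no_stop_inframe(seq, frame=0):
    return all(seq[i:i + 3] not in STOPS for i in range(frame, len(seq) - 2, 3))


def make_v(length=72, anchor_tail=6):
    """V body + Cys anchor codon + anchor_tail nt, frame 0, no in-frame stop."""
    while True:
        anchor_start = length - 3 - anchor_tail
        assert anchor_start % 3 == 0
        seq = rand_nt(anchor_start) + str(rng.choice(["TGT", "TGC"])) + rand_nt(anchor_tail)
        if no_stop_inframe(seq):
            return seq, anchor_start


def make_j(head=9, tail=21, anchor=None):
    """head nt (trimmable) + Phe/Trp anchor + Gly codon + tail nt."""
    while True:
        gly = str(rng.choice(["GGA", "GGC", "GGG", "GGT"]))
        seq = rand_nt(head) + (anchor or str(rng.choice(["TTT", "TTC"]))) + gly + rand_nt(tail)
        if no_stop_inframe(seq, frame=head % 3):
            return seq, head


segs = []
for chain, vs, js in [
    ("TRA",
     ["TRAV1", "TRAV3", "TRAV6", "TRAV9", "TRAV11", "TRAV12D-1", "TRAV14", "TRAV16"],
     ["TRAJ12", "TRAJ18", "TRAJ22", "TRAJ27", "TRAJ33", "TRAJ40"]),
    ("TRB",
     ["TRBV1", "TRBV2", "TRBV13-1", "TRBV19"],
     ["TRBJ1-1", "TRBJ1-4", "TRBJ2-1", "TRBJ2-7"]),
]:
    for name in vs:
        seq, anchor = make_v()
        segs.append(SegmentRecord(name, "01", "V", chain, seq, anchor, anchor % 3))
    for name in js:
        # TRAJ33 carries the J-TRP anchor (mouse MAIT junctions end in W)
        seq, anchor = make_j(anchor="TGG" if name == "TRAJ33" else None)
        segs.append(SegmentRecord(name, "01", "J", chain, seq, anchor, anchor % 3))

db = ReferenceDB(segs)
write_reference(db, "src/tcrpipe/data/toy_reference.fasta", "src/tcrpipe/data/toy_anchors.tsv")
print(f"wrote {len(db)} segments")
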