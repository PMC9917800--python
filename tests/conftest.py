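import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from tcrpipe import (ReadRecord, SimulationConfig, annotate_reads,
                     generate_reads, simulate_repertoire, toy_reference)

#: the three invariant/antigen-associated spike-ins exercised throughout
SPIKE_INS = [
    ("TRAV11", "TRAJ18", "CVVGDRGSALGRLHF", 0.15),   # mouse iNKT
    ("TRAV1", "TRAJ33", "CAVRDSNYQLIW", 0.05),       # mouse MAIT
    ("TRAV12D-1", "TRAJ22", "CALSEKSSGSWQLIF", 0.05),
]


@pytest.fixture(scope="session")
def db():
    return toy_reference()


@pytest.fixture(scope="session")
def clean_cfg():
    return SimulationConfig(n_clones=30, read_count=2000, error_rate=0.0,
                            seed=7, spike_ins=list(SPIKE_INS))


@pytest.fixture(scope="session")
def clean_sim(db, clean_cfg):
    """(clones, reads, truth) for a zero-error 2000-read repertoire."""
    clones = simulate_repertoire(clean_cfg, db)
    reads, truth = generate_reads(clones, clean_cfg, db)
    return clones, reads, truth


@pytest.fixture(scope="session")
def clean_annotated(db, clean_sim):
    _, reads, _ = clean_sim
    return annotate_reads([ReadRecord(r, s) for r, s, _ in reads], db)
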