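"""Simulator ground truth: spike-ins, abundances, determinism, error model."""

import numpy as np
import pytest

from tcrpipe import SimulationConfig, generate_reads, simulate_repertoire
from tcrpipe.errors import SimulationError, TcrPipeError
from tcrpipe.simulate import clone_amplicon, clone_table
from tcrpipe.cdr3 import translate

from conftest import SPIKE_INS


def test_spike_in_carries_requested_clonotype(db):
    cfg = SimulationConfig(n_clones=5, seed=1,
                           spike_ins=[("TRAV11", "TRAJ18",
                                       "CVVGDRGSALGRLHF", 0.2)])
    clones = simulate_repertoire(cfg, db)
    spike = clones[0]
    assert (spike.v_gene, spike.j_gene, spike.cdr3_aa) == \
        ("TRAV11", "TRAJ18", "CVVGDRGSALGRLHF")
    assert spike.true_frequency == pytest.approx(0.2)
    # junction is reconstructible from the construction parameters
    amplicon = clone_amplicon(spike, db)
    assert spike.cdr3_nt in amplicon
    assert translate(spike.cdr3_nt) == "CVVGDRGSALGRLHF"


def test_single_clone_gets_full_frequency(db):
    clones = simulate_repertoire(SimulationConfig(n_clones=1, seed=2), db)
    assert len(clones) == 1
    assert clones[0].true_frequency == pytest.approx(1.0)


def test_clone_count_and_frequency_normalization(db, clean_cfg):
    clones = simulate_repertoire(clean_cfg, db)
    assert len(clones) == clean_cfg.n_clones + len(clean_cfg.spike_ins)
    assert sum(c.true_frequency for c in clones) == pytest.approx(1.0, abs=1e-9)
    keys = {c.key for c in clones}
    assert len(keys) == len(clones)  # distinct (V, J, CDR3aa)


def test_same_seed_same_output(db, clean_cfg):
    a = clone_table(simulate_repertoire(clean_cfg, db))
    b = clone_table(simulate_repertoire(clean_cfg, db))
    assert a.equals(b)
    ra, ta = generate_reads(simulate_repertoire(clean_cfg, db), clean_cfg, db)
    rb, tb = generate_reads(simulate_repertoire(clean_cfg, db), clean_cfg, db)
    assert ra == rb and ta.equals(tb)


def test_productive_junctions_well_formed(db, clean_sim):
    clones, _, _ = clean_sim
    for c in clones:
        assert c.productive
        assert len(c.cdr3_nt) % 3 == 0
        aa = translate(c.cdr3_nt)
        assert aa == c.cdr3_aa
        assert aa[0] == "C" and aa[-1] in "FW" and "*" not in aa
        # junction_nt = cdr3 + the following Gly codon
        assert c.junction_nt[:-3] == c.cdr3_nt
        assert translate(c.junction_nt[-3:]) == "G"


def test_zero_error_reads_equal_amplicon(db):
    cfg = SimulationConfig(n_clones=1, read_count=10, error_rate=0.0, seed=5)
    clones = simulate_repertoire(cfg, db)
    reads, truth = generate_reads(clones, cfg, db)
    amplicon = clone_amplicon(clones[0], db)
    assert len(reads) == 10
    assert all(seq == amplicon for _, seq, _ in reads)
    assert set(truth["clone_id"]) == {clones[0].clone_id}


def test_substitution_rate_matches_binomial(db):
    """Observed mismatches vs the truth amplicon within 3 sigma of
    Binomial(total_bases, error_rate)."""
    rate = 0.01
    cfg = SimulationConfig(n_clones=1, read_count=150, error_rate=rate, seed=9)
    clones = simulate_repertoire(cfg, db)
    reads, _ = generate_reads(clones, cfg, db)
    amplicon = clone_amplicon(clones[0], db)
    total = sum(len(seq) for _, seq, _ in reads)
    mismatches = sum(a != b for _, seq, _ in reads
                     for a, b in zip(seq, amplicon))
    assert total >= 10_000  # >= 10 kb sequenced, as the oracle assumes
    sigma = np.sqrt(total * rate * (1 - rate))
    assert abs(mismatches - total * rate) <= 3 * sigma


def test_read_counts_match_multinomial(db):
    """Per-clone read counts within 3 sigma of n*p for a 0.7/0.3 pair."""
    cfg = SimulationConfig(n_clones=1, read_count=1000, seed=13,
                           spike_ins=[("TRAV11", "TRAJ18",
                                       "CVVGDRGSALGRLHF", 0.7)])
    clones = simulate_repertoire(cfg, db)
    assert [round(c.true_frequency, 6) for c in clones] == [0.7, 0.3]
    _, truth = generate_reads(clones, cfg, db)
    counts = truth["clone_id"].value_counts()
    for clone in clones:
        n, p = cfg.read_count, clone.true_frequency
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts.get(clone.clone_id, 0) - n * p) <= 3 * sigma


def test_truth_table_covers_every_read(db, clean_sim):
    _, reads, truth = clean_sim
    assert list(truth["read_id"]) == [r for r, _, _ in reads]


@pytest.mark.parametrize("bad_cfg,match", [
    (dict(read_count=0), "read_count"),
    (dict(error_rate=1.5), "error_rate"),
    (dict(spike_ins=[("TRAV11", "TRAJ18", "CVVGDRGSALGRLHF", 0.6),
                     ("TRAV1", "TRAJ33", "CAVRDSNYQLIW", 0.5)]), "sum"),
])
def test_config_validation(db, bad_cfg, match):
    base = dict(n_clones=2, seed=1)
    base.update(bad_cfg)
    with pytest.raises(SimulationError, match=match):
        cfg = SimulationConfig(**base)
        clones = simulate_repertoire(cfg, db)
        generate_reads(clones, cfg, db)


def test_unplaceable_spike_rejected(db):
    # CDR3 ending in W cannot come from TRAJ18 (Phe anchor)
    with pytest.raises(SimulationError, match="anchor"):
        simulate_repertoire(SimulationConfig(
            n_clones=1, seed=1,
            spike_ins=[("TRAV11", "TRAJ18", "CVVGDRGSALGRLHW", 0.1)]), db)
    with pytest.raises(TcrPipeError, match="unknown segment"):
        simulate_repertoire(SimulationConfig(
            n_clones=1, seed=1,
            spike_ins=[("TRAV77", "TRAJ18", "CVVF", 0.1)]), db)


def test_powerlaw_abundance_model(db):
    cfg = SimulationConfig(n_clones=20, abundance_model="powerlaw", seed=4)
    clones = simulate_repertoire(cfg, db)
    freqs = sorted(c.true_frequency for c in clones)
    assert sum(freqs) == pytest.approx(1.0)
    assert freqs[-1] > 10 * freqs[0]  # strongly skewed


def test_trb_simulation_keys_on_v_j_cdr3(db):
    cfg = SimulationConfig(n_clones=8, chain="TRB", read_count=50, seed=21)
    clones = simulate_repertoire(cfg, db)
    assert all(c.v_gene.startswith("TRBV") and c.j_gene.startswith("TRBJ")
               for c in clones)
    reads, truth = generate_reads(clones, cfg, db)
    assert set(truth.columns) == {"read_id", "clone_id", "v_gene", "j_gene",
                                  "cdr3_aa"}
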