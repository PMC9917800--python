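"""Clonotype aggregation, ranking, frequencies and usage matrices."""

import random

import numpy as np
import pandas as pd
import pytest

from tcrpipe import aggregate_clonotypes, gene_usage, top_n
from tcrpipe.align import SegmentHit
from tcrpipe.clonotypes import usage_long
from tcrpipe.errors import EmptyRepertoireError
from tcrpipe.records import AnnotatedRead

import oracles


def _hit(gene):
    return SegmentHit(gene_name=gene, allele="01", score=50, read_start=0,
                      read_end=10, seg_start=0, seg_end=10, identity=1.0)


def _read(i, v, j, aa, reason="none", productive=True):
    return AnnotatedRead(
        read_id=f"r{i}", sequence="ACGT", v_hit=_hit(v), j_hit=_hit(j),
        cdr3_nt="TGT" * len(aa) if aa else "", cdr3_aa=aa,
        productive=productive, fail_reason=reason,
    )


def test_simple_counting_and_ranking():
    reads = [_read(i, "TRAV11", "TRAJ18", "CVVF") for i in range(3)]
    reads.append(_read(3, "TRAV1", "TRAJ33", "CAVW"))
    table = aggregate_clonotypes(reads)
    a = table.iloc[0]
    assert (a.v_gene, a.copy_count, a.frequency_pct, a["rank"]) == \
        ("TRAV11", 3, 75.0, 1)
    b = table.iloc[1]
    assert (b.v_gene, b.copy_count, b.frequency_pct, b["rank"]) == \
        ("TRAV1", 1, 25.0, 2)


def test_single_clonotype_is_rank_one_at_100_pct():
    table = aggregate_clonotypes([_read(0, "TRAV1", "TRAJ18", "CAVF")])
    assert len(table) == 1
    assert table.iloc[0]["frequency_pct"] == 100.0
    assert table.iloc[0]["rank"] == 1


def test_empty_repertoire_is_an_error():
    with pytest.raises(EmptyRepertoireError, match="empty repertoire"):
        aggregate_clonotypes([_read(0, "TRAV1", "TRAJ18", "", reason="no_v",
                                    productive=False)])


def test_matches_counting_oracle_on_simulation(clean_annotated):
    """Pipeline table equals an independent hash-and-count oracle exactly."""
    table = aggregate_clonotypes(clean_annotated)
    keys = [(ar.v_hit.gene_name, ar.j_hit.gene_name, ar.cdr3_aa)
            for ar in clean_annotated if ar.productive]
    expected = pd.DataFrame(oracles.count_clonotypes(keys))
    pd.testing.assert_frame_equal(
        table[expected.columns].reset_index(drop=True), expected,
    )


def test_conservation_and_permutation_invariance(clean_annotated):
    table = aggregate_clonotypes(clean_annotated)
    eligible = sum(1 for ar in clean_annotated if ar.productive)
    assert int(table["copy_count"].sum()) == eligible
    assert table["frequency_pct"].sum() == pytest.approx(100.0, abs=1e-6)
    shuffled = list(clean_annotated)
    random.Random(5).shuffle(shuffled)
    pd.testing.assert_frame_equal(aggregate_clonotypes(shuffled), table)


def test_duplicating_reads_doubles_counts_not_frequencies(clean_annotated):
    once = aggregate_clonotypes(clean_annotated)
    twice = aggregate_clonotypes(list(clean_annotated) * 2)
    assert (twice["copy_count"].to_numpy()
            == 2 * once["copy_count"].to_numpy()).all()
    np.testing.assert_allclose(twice["frequency_pct"], once["frequency_pct"])


def test_rank_ties_break_lexicographically():
    reads = [_read(0, "TRAV9", "TRAJ12", "CAF"),
             _read(1, "TRAV3", "TRAJ12", "CAF"),
             _read(2, "TRAV3", "TRAJ12", "CAW")]
    table = aggregate_clonotypes(reads)
    assert list(table["rank"]) == [1, 2, 3]
    assert list(table["v_gene"]) == ["TRAV3", "TRAV3", "TRAV9"]
    assert list(table["cdr3_aa"]) == ["CAF", "CAW", "CAF"]


def test_j_usage_marginalizes_to_100_for_shared_j():
    reads = [_read(i, "TRAV11", "TRAJ18", "CVVF") for i in range(3)]
    reads += [_read(i + 3, "TRAV1", "TRAJ18", "CAVF") for i in range(2)]
    table = aggregate_clonotypes(reads)
    j_usage = gene_usage(table, level="J")
    assert j_usage["TRAJ18"] == pytest.approx(100.0)
    v_usage = gene_usage(table, level="V")
    assert v_usage["TRAV11"] == pytest.approx(60.0)
    assert v_usage["TRAV1"] == pytest.approx(40.0)


def test_usage_matrix_invariants_and_oracle(clean_annotated):
    table = aggregate_clonotypes(clean_annotated)
    matrix = gene_usage(table, level="VxJ")
    assert (matrix.to_numpy() >= 0).all()
    assert matrix.to_numpy().sum() == pytest.approx(100.0, abs=1e-6)
    # row/column sums equal the per-gene marginals
    v_usage = gene_usage(table, level="V")
    for v in matrix.index:
        assert matrix.loc[v].sum() == pytest.approx(v_usage[v])
    # cells equal an oracle recount over raw reads
    keys = [(ar.v_hit.gene_name, ar.j_hit.gene_name) for ar in clean_annotated
            if ar.productive]
    total = len(keys)
    for (v, j), n in pd.Series(keys).value_counts().items():
        assert matrix.loc[v, j] == pytest.approx(100.0 * n / total)
    long = usage_long(matrix)
    assert long["pct"].sum() == pytest.approx(100.0, abs=1e-6)


def test_spiked_vj_cell_near_truth(db, clean_cfg, clean_annotated):
    """The dominant spiked V-J combination lands within 3 sigma of its
    true multinomial expectation."""
    matrix = gene_usage(aggregate_clonotypes(clean_annotated), level="VxJ")
    p = clean_cfg.spike_ins[0][3]
    n = clean_cfg.read_count
    sigma_pct = 100.0 * np.sqrt(p * (1 - p) / n)
    # other background clones can share TRAV11-TRAJ18, so the cell may only
    # exceed the spike's own expectation by chance background mass
    assert matrix.loc["TRAV11", "TRAJ18"] >= 100.0 * p - 3 * sigma_pct


def test_top_n_truncation_and_oracle_order(clean_annotated):
    table = aggregate_clonotypes(clean_annotated)
    assert len(top_n(table.head(5), 30)) == 5
    assert len(top_n(table, 1)) == 1
    t30 = top_n(table, 30)
    keys = [(ar.v_hit.gene_name, ar.j_hit.gene_name, ar.cdr3_aa)
            for ar in clean_annotated if ar.productive]
    expected = pd.DataFrame(oracles.count_clonotypes(keys)).head(30)
    assert list(map(tuple, t30[["v_gene", "j_gene", "cdr3_aa"]].to_numpy())) \
        == list(map(tuple, expected[["v_gene", "j_gene", "cdr3_aa"]].to_numpy()))
    with pytest.raises(ValueError, match="n must be"):
        top_n(table, 0)


def test_unproductive_reads_counted_only_on_request():
    reads = [_read(0, "TRAV1", "TRAJ18", "CAVF"),
             _read(1, "TRAV1", "TRAJ18", "CA*F", reason="stop_codon",
                   productive=False)]
    assert int(aggregate_clonotypes(reads)["copy_count"].sum()) == 1
    both = aggregate_clonotypes(reads, include_unproductive=True)
    assert int(both["copy_count"].sum()) == 2


def test_usage_surface_plot_writes_image(tmp_path, clean_annotated):
    from tcrpipe.clonotypes import plot_usage_3d
    matrix = gene_usage(aggregate_clonotypes(clean_annotated), level="VxJ")
    out = tmp_path / "usage.png"
    plot_usage_3d(matrix, str(out), title="TRA V x J usage")
    assert out.stat().st_size > 0
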