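# tcrpipe

T-cell receptor (TCR) repertoire clonotyping from V–junction–J amplicon
reads, for immunologists profiling which T-cell clones infiltrate a tissue —
e.g. comparing allergen-sensitized and control mice across oral mucosa and
draining lymph nodes over a time course.

## What it computes

Amplicon sequencing of the rearranged TCR α (TRA) or β (TRB) locus yields
reads spanning a germline V segment, the hypervariable junction, and a J
segment.  `tcrpipe` re-implements the standard analysis chain:

1. **V/J assignment** — each read is aligned (Smith–Waterman, affine gaps)
   against every candidate segment of an IMGT-style reference; the
   best-scoring V and J win, with deterministic tie-breaking.
2. **CDR3 extraction** — the junction is delimited by the conserved anchors
   of the IMGT unique numbering: the V segment's 2nd-CYS (position 104)
   through the J segment's J-PHE/J-TRP (position 118), both inclusive, with
   the following Gly (position 119) required in the read as a frame check.
   Anchor positions are curated reference metadata projected onto the read
   through the alignments; the junction is translated and called productive
   when it is in frame, stop-free and C…F/W-bounded.
3. **Clonotyping** — a *clonotype* is the class of reads sharing
   (V gene, J gene, CDR3 amino-acid sequence).  Copies are counted per
   class, ranked, and expressed as percentage frequencies; V×J usage
   matrices summarize gene-segment usage (cells sum to 100%).
4. **Comparison** — clonotype tables from several samples are cross-tabulated
   (absent entries rendered `N.D.`, not detected), single clonotypes are
   tracked over time, and invariant T-cell clonotypes are labelled from
   gene-segment rules: mouse iNKT = TRAV11(d)–TRAJ18, mouse MAIT =
   TRAV1–TRAJ33, with the canonical junctions
   (`CVVGDRGSALGRLHF`, `CAVRDSNYQLIW`) attached as optional confirmations.

Because public repositories rarely hold the raw amplicons behind published
repertoire tables, the package also ships a **ground-truthed V(D)J
simulator**: skewed (lognormal) clone abundances, exonuclease-style V/J
trimming, untemplated N-insertions, per-base substitution error, and exact
spike-ins of clonotypes of interest by reverse translation.  Every emitted
read is linked to its generating clone, so the full pipeline is validated
end to end against known truth.

## Worked example

```bash
cat > sim.yaml <<EOF
n_clones: 20
read_count: 2000
error_rate: 0.002
seed: 11
spike_ins:
  - [TRAV11, TRAJ18, CVVGDRGSALGRLHF, 0.25]
  - [TRAV12D-1, TRAJ22, CALSEKSSGSWQLIF, 0.10]
EOF
tcrpipe simulate --config sim.yaml --out-prefix om
tcrpipe annotate --reads om.fastq --out-dir om_out
head -6 om_out/top.tsv
```

prints

```
wrote 2000 reads from 22 clones to om.fastq
1965/2000 reads pass; 71 clonotypes -> om_out/
rank  v_gene     j_gene  cdr3_aa          frequency_pct
1     TRAV11     TRAJ18  CVVGDRGSALGRLHF  22.60
2     TRAV9      TRAJ18  CGRLF            15.11
3     TRAV16     TRAJ12  CRPDCQF          10.28
4     TRAV12D-1  TRAJ22  CALSEKSSGSWQLIF  9.67
5     TRAV16     TRAJ33  CTGFRW           9.67
```

The spiked iNKT-like clonotype, simulated at 25% of the repertoire, is
recovered at rank 1 with an estimated frequency of 22.60% (its sampled share
after 0.2% sequencing error diverts some reads into singleton error
clonotypes — hence 71 observed clonotypes from 22 true clones).  The
`om_out/` bundle also contains the per-read AIRR Rearrangement table, the
full clonotype table, V/J/V×J usage tables and a `manifest.json` that
accounts for every input read.  `tcrpipe compare --samples a.tsv --samples
b.tsv` then cross-tabulates samples and labels invariant clonotypes.

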