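# Methods

## Scope and model

`tcrpipe` analyses merged single-sequence TCR amplicons that span
V segment → junction → J segment in a fixed orientation (the product of
5′-adaptor-ligation amplicon chemistry after read-pair merging; merging
itself is upstream preprocessing and out of scope).  TRA is the primary
target; TRB runs through the same machinery keyed on (V, J, CDR3) — D-derived
nucleotides are treated as part of the untemplated insert, matching how
β-chain clones are conventionally reported at V–J–CDR3 resolution.

A clonotype is the equivalence class of reads sharing V gene, J gene and
CDR3 amino-acid sequence.  Gene-level names are used (alleles compete during
alignment but collapse in the clonotype key); amino-acid-level CDR3 identity
is the default, with nucleotide-level grouping behind a flag.

## Reference and anchors

The segment reference is a FASTA plus a sidecar anchor table giving each
segment's conserved-anchor codon: 2nd-CYS (IMGT position 104) for V, J-PHE /
J-TRP (position 118) for J.  Anchors are treated as curated facts — they are
validated (V ∈ {TGT, TGC}; J ∈ {TTT, TTC, TGG}) but never inferred by motif
scanning of the reference.  All internal coordinates are 0-based half-open;
IMGT position labels appear only in documentation.  Which IMGT release to
use is deliberately left to the user: the reference is an input, not a
constant.  The bundled toy reference (8 TRA V, 6 TRA J, 4+4 TRB) has
randomly generated but anchor-valid bodies; segment names mirror real mouse
genes, so invariant-clonotype logic is exercisable offline.  It is
synthetic: results on it say nothing about real gene-assignment ambiguity
between homologous alleles (real TRAV paralogues are far more similar than
random 72-mers).

## Segment assignment

Reads are aligned locally (Smith–Waterman, affine gaps) against every
candidate segment via biotite's optimal aligner; scoring is match +2,
mismatch −2, gap open −4, gap extend −1, where a length-n gap costs
`open + (n−1)·extend`.  Thresholds (min V score 40, min J score 24, min
identity 0.85) were chosen once so the bundled reference's segments are
cleanly separable; all are exposed in `AssignmentParams`.  The scoring
scheme is an explicit stand-in — commercial repertoire services do not
publish theirs — and the whole scheme is config, not biology.

Ties on score break by higher identity, then longer aligned span, then
lexicographically smallest gene name, making assignment reproducible across
platforms.  Reads are scanned on one strand by default (amplicons have fixed
orientation); `both_strands` annotates the reverse complement too and keeps
the orientation with the higher combined V+J score.

V and J are assigned independently.  Their aligned blocks may overlap by a
few nucleotides on perfectly clean reads: a local alignment happily extends
over the segment's trimmed tail plus a gap when chance matches pay for it
(worst case ≈ trim + gap slack ≈ 20 nt).  Such overlap cannot move the
anchors, which project from deep inside each block, so only segment-scale
disorder (> `max_vj_overlap` = 30 nt, e.g. a J block before or inside the V
block) is flagged `vj_overlap` as a chimera.

## CDR3 extraction

The junction is anchor-inclusive: Cys(104) codon through Phe/Trp(118) codon.
The codon immediately after the J anchor must translate to Gly(119); it
validates the frame but is not part of the junction.  Anchor codons are
projected through the alignment traces; if an anchor base aligns to a gap or
falls outside the aligned block the read fails (`no_anchor_c` /
`no_anchor_fg`) rather than guessing a shifted anchor — conservative by
design, since the junction is defined only by intact anchors.  A projected
span not divisible by 3 fails `out_of_frame`.  Junctions whose read sequence
no longer starts with Cys or ends with Phe/Trp (sequencing errors can destroy
an anchor that still projects cleanly) fail with the same anchor codes.
In-frame junctions containing a stop codon are retained with
`fail_reason=stop_codon` and `productive=False`; clonotype counting uses
productive reads only unless `include_unproductive` is set (whether
unproductive rearrangements belong in published frequencies is generally
unstated; productive-only is the default here).

## Clonotype statistics

Copy counts are reads per clonotype; the denominator for every percentage is
the set of reads passing V + J + CDR3 extraction (and productivity, unless
overridden).  Ranks sort by copy count descending with lexicographic
(v, j, cdr3) tie-break.  V×J usage matrices are read-weighted by default
(each read counts once; cells sum to 100%); unique-clonotype weighting is a
flag, since published 3D usage surfaces rarely state which convention they
use.  Text outputs print frequencies to 2 decimals; full precision is kept
internally, so the printed column may sum to slightly less than 100 while
the internal invariant holds to 1e-6.

## Cross-sample comparison

The shared-clonotype table is the outer join of per-sample tables on the
clonotype key; absent cells are NaN internally and the literal `N.D.` in
text output.  Rows order by max (or mean) frequency.  Each input table is
one sample; pooling replicates is left to the user.  Invariant definitions
use a V-gene *prefix* match (so `TRAV11` also matches the `TRAV11d` spelling
variant) plus exact J equality; the canonical CDR3 is carried as an optional
confirmation and only enforced when `cdr3_required` is set.  Note the MAIT
pattern `TRAV1` is also a prefix of `TRAV11…`/`TRAV12…`; the exact-J
requirement (TRAJ33) is what keeps the default definitions specific.

## Simulator

The simulator emulates the statistical structure the analysis assumes, not
any particular instrument:

* **Abundances** — lognormal(μ=0, σ=1.5) weights renormalized to sum to 1
  (a power law with α=1.5 is the alternative).  This produces the strongly
  skewed, top-30-dominated spectra typical of infiltrating-T-cell
  repertoires.  No published junction or depth statistics back these
  defaults; they are documented, overridable choices.
* **Junctions** — V 3′ and J 5′ trims ~ Uniform{0..6}; N-insert length ~
  Geometric(p=0.4) on support {0, 1, …}; insert bases i.i.d. uniform.
  Productive-only mode resamples until the junction is in frame, stop-free,
  ≥ 3 codons and C…F/W-bounded; background clones are drawn with distinct
  clonotype keys.
* **Spike-ins** — a requested (V, J, CDR3aa, frequency) is built by keeping
  exactly the V anchor codon and the J anchor onward as templated ends and
  reverse-translating interior residues with the lexicographically smallest
  codon each, which makes the construction deterministic.  Requests whose
  last residue contradicts the J anchor (e.g. a W junction on a Phe-anchor
  J) are hard errors.
* **Reads** — multinomial sampling of `read_count` reads by true frequency;
  i.i.d. substitution errors at `error_rate` (no indels — real MiSeq indel
  rates are far below substitution rates in amplicons and are not modelled);
  constant Q40 quality; no PCR bias, UMIs or paired-end structure.  A truth
  table links every read to its clone.

All randomness flows from the config seed; identical configs give
byte-identical outputs.

What passing on simulated data does **not** show: robustness to indels and
homopolymer artefacts, to PCR amplification bias, to cross-mapping between
near-identical real alleles, or to primer/adaptor carry-over.  The test
suite demonstrates correctness of the analysis logic under its stated error
model, not field performance on arbitrary libraries.

## Numerical and validation choices

* Frequencies renormalize exactly; Σ frequency = 100% to 1e-6 and
  Σ copy_count equals the eligible-read count (asserted in tests and in
  every run manifest, which also checks input = pass + per-reason failures).
* The aligner is cross-checked against an independent hand-written
  exhaustive Gotoh dynamic program (plain loops) on simulated reads and on
  arbitrary hypothesis-generated sequence pairs; anchor projection is
  cross-checked against the closed-form junction coordinates implied by each
  clone's construction parameters.
* Validation problem sizes: 10,000 zero-error reads for exact-recovery and
  frequency checks, 200 noisy reads for oracle equivalence, 5,000 reads at
  0.5% error for robustness (V/J accuracy and spike-in top-30 ranks), three
  1,500-read samples for the cross-sample `N.D.` structure.  Statistical
  assertions use 3σ multinomial/binomial bounds; where one bound is tested
  per clone across many clones, the expected number of 3σ excursions under
  the null is itself > 0, so outliers are capped at their calibrated
  expectation instead of asserted to zero.

## Known limitations

* No D-segment calling for TRB; no FR/CDR1/CDR2 delineation or full IMGT
  unique numbering of the V domain.
* Indel sequencing errors shift the junction frame and are rejected rather
  than corrected; high-indel platforms would need realignment-based rescue.
* No diversity indices or between-group statistics — the package produces
  the tables such analyses consume.
* The bundled reference is synthetic; real analyses must supply an IMGT
  reference with curated anchor positions.
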