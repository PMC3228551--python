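# Methods

## Model and assumptions

The search treats mutually exclusive splicing as a constraint-satisfaction
problem on the gene structure. A candidate replacement for a query exon
must be able to splice into the transcript exactly where the query exon
does, which imposes:

* **Splice-pattern conservation.** The intron preceding the candidate must
  end with an acceptor compatible with the donor of the intron preceding
  the query exon, and symmetrically at the 3' side. Only the four patterns
  GT—AG, GC—AG, GG—AG, AT—AC are admitted; AT pairs exclusively with AC.
  No splice-site strength model (PWM, MaxEnt) is used: compatibility is
  purely the dinucleotide patterns.
* **Reading-frame conservation.** The candidate inherits the query's start
  phase; its length must differ from the query's by whole codons only, so
  the end phase matches automatically and split codons are preserved.
* **Coding plausibility.** The candidate, translated in the query's frame
  with split codons completed from the flanking constitutive exons, must be
  stop-free.
* **Homology.** The candidate's translation must align to the query's with
  a relative score at or above a threshold.

These constraints assume the input structure is a correct protein-coding
gene model on an assembled genomic sequence. Frame-shifted homologs,
pseudo-exons with in-frame stops, and exons whose length diverged beyond
the window are invisible to the search by design.

## Coordinates, phases and strand handling

All internal coordinates are 0-based half-open on a forward-normalized
axis; GFF3 I/O converts to and from 1-based inclusive coordinates.
Minus-strand transcripts are reverse-complement-normalized when loaded, so
the entire search is strand-free and strand invariance is a testable
property rather than a code path. Phases follow the GFF3 CDS convention
(nucleotides preceding the first complete codon); they are recomputed from
the exon lengths and checked against file phases when present.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| allowed_length_difference | aa | 20 | half-width of the candidate length window |
| min_score | fraction | 0.15 | relative-score acceptance threshold |
| min_exon_length | aa | 15 | query exons shorter than this are not searched |
| max_recursion_depth | rounds | 0 (≤ 3) | repeated search with found exons as queries |
| search_all_introns | — | off | scan every intron instead of the surrounding two |
| search_updownstream | — | off | add up/downstream windows for terminal exons |
| region_size | nt | 10 000 | width of the up/downstream windows |
| search_with_start_codon | mode | auto | ATG anchoring of first-exon candidates; auto = on iff the protein starts with M |
| search_with_stop_codon | mode | auto | stop anchoring of last-exon candidates; auto = on iff a stop codon follows the last exon |
| min_new_intron_length | nt | 4 | shortest intron a candidate may imply |
| gap_open / gap_extend | score | −10 / −2 | affine gap model (see below) |

`region_size` has no published default; 10 kb covers typical tandem-copy
distances without flooding terminal clusters with remote homologs.
`min_new_intron_length` defaults to the permissive floor of 4 nt — just
room for both splice dinucleotides — because nothing in the model bounds
it; both are configurable.

## Alignment and scoring

Scores come from a global (Needleman–Wunsch-style, terminal gaps
penalized) alignment with affine gap costs in the Gotoh sense, computed by
Biopython's `PairwiseAligner` configured so that a gap run of length ℓ
costs `gap_open + (ℓ−1)·gap_extend` = −10 − 2(ℓ−1). This convention is
pinned by hand-derived examples ("MA"/"MA" = 9, "MA"/"M" = −5) and by an
exhaustive alignment-enumeration oracle in the test suite; other
implementations sometimes charge open+extend for the first gap position,
which would shift every gapped score.

Relative score = raw score / query self-score. Blosum62 is
diagonal-dominant over the 20 standard residues (verified
programmatically), so relative scores never exceed 1.0; the X row is not
dominant, but X cannot occur because candidate bodies containing N are
rejected at enumeration (and >50% X translations are dropped as a
degenerate-input guard). The threshold comparison uses ≥ with a 1e-9
tolerance. Overlap resolution sorts by (relative score desc, DNA length
desc, leftmost start) — the last key makes ties deterministic — and keeps
a candidate iff it overlaps no kept candidate; the result is independent
of input order.

The query's split-codon completions (taken from its neighbouring
constitutive exons) are reused for every candidate of the cluster, so all
members are scored over the same completed codon positions and scores are
comparable. Candidates never search for their own phase.

## Search scope and recursion

By default each internal exon searches its two surrounding introns;
`search_all_introns` widens this to every intron, and with
`search_updownstream` additionally to the two flanking windows (terminal
exons always get their window when `search_updownstream` is set; internal
exons get the windows only in combination with `search_all_introns`, the
scope used to recognize tandem gene arrays). A query exon's own locus is
never its own candidate; candidates coinciding exactly with another
annotated exon are kept and flagged — that is how *trans*-spliced groups
surface. Terminal exons whose anchor is unavailable (non-M protein, or no
following stop, under auto mode) are skipped with a logged warning, as are
exons whose flanking introns carry non-canonical dinucleotides.

Recursion re-searches the same regions as the top-level run, using each
newly accepted member (its translation, its inherited frame, its own
self-score) as the query. New candidates are deduplicated by exact genomic
interval and merged under overlap resolution in which existing members
always win; members are never removed, so the member set is monotone in
the recursion depth. A fixed point may end the recursion before the depth
bound.

## Group-pattern detection

With all-introns scope, candidates of ≥ 2 consecutive query exons that can
be chained in query order — consecutive chain members at most
`region_size` apart with no annotated exon between them — indicate a
parallel copy of part of the gene: a tandem duplication or a
*trans*-spliced group. Such clusters are re-labelled `group_pattern`
rather than reported as independent MXE clusters. The threshold of two
consecutive exons is the minimal pattern that distinguishes a parallel
group from an isolated candidate; it is configurable
(`group_min_consecutive`). The package deliberately does not decide
between tandem duplication and *trans*-splicing — that distinction needs
evidence (synteny, ESTs) outside the gene structure.

## Annotation screen

`screen_structures` runs the search over every multi-exon transcript
(sequentially, in deterministic transcript order; the per-transcript
searches are independent, so the order only affects bookkeeping) and pools
per-transcript clusters per gene by shared member intervals.
Annotation-defined MXE clusters are maximal runs of non-universal exon
loci whose per-locus transcript sets partition the gene's transcripts;
runs partitioning in blocks of ≥ 2 exons per transcript are group-type and
their genes are excluded from the agreement analysis automatically.
Unflanked clusters are separated into multiple-promoter (first exons) and
multiple-poly(A) (last exons) types. "Same reading frame" in the
neighbour-exon scan is implemented as equal start phases — the only frame
attribute adjacent exons share — and the pair score is normalized by the
upstream exon's self-score. Sensitivity is exactly-matched annotated
internal members over all annotated internal members; specificity is
matched predictions over all predicted internal candidate exons;
predictions overlapping annotation without an exact border match are
tallied separately.

## Synthetic fixtures

The generator builds genes codon-wise: a random protein (starting with M)
is back-translated through uniformly chosen synonymous codons, so the CDS
is stop-free by construction; introns are canonical GT…AG with uniform
background at a configurable GC content; a stop codon follows the last
exon. Implanted homologs receive compatible splice dinucleotides (an ATG
start for first-exon copies, a following TAA for last-exon copies) and
diverge by amino-acid substitutions sampled uniformly over the 19
alternative residues — no Blosum-biased mutation, so recovery curves read
as a function of raw identity — and by whole-codon indels; split-codon
edge codons are never mutated so the copy stays frame- and
completion-compatible. Ground-truth tables record exact intervals and
identities. All randomness flows from one explicit seed; no global state.

What the fixtures do *not* emulate: splice-site strength variation,
branch points and polypyrimidine tracts, biased codon usage, repeats, GC
heterogeneity along real introns, and untranslated exons. Passing tests
therefore demonstrate the correctness of the constraint logic and scoring
on clean structures, not calibration of the false-positive rate on real
genomes: the spurious-candidate load of a uniform-background intron is a
lower bound on what a repeat-rich genome produces.

## Problem sizes in tests and the acceptance script

The enumeration oracle runs 1 000 random instances with regions of
50–2 000 nt; the alignment oracle covers all 116 281 sequence pairs of
length ≤ 4 over {A, R, N, D}; implant recovery uses 60–70 fixtures per
divergence level with clusters of 2–6 copies in 760-nt introns; the screen
fixture plants 3 internal MXE pairs and 1 terminal-alternative pair among
10 genes. These sizes give stable percentages while keeping a full run in
well under a minute per block on one CPU.

## Known limitations

* Gene structures are taken as given; no protein-to-genome alignment is
  performed to build or correct them.
* Only the standard genetic code is supported.
* The relative score of a recursion-round member is relative to the member
  that found it, not to the original query.
* `AnnotatedMxeCluster` extraction assumes alternative loci do not
  interleave with constitutive loci in genomic order; exotic nestings are
  not claimed.
* Candidates never span region boundaries, so an alternative exon
  straddling an annotated exon cannot be proposed.
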