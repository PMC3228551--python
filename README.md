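# mxefinder

Prediction of mutually exclusive spliced exons (MXEs) from genomic sequence
and exon–intron gene structures.

Mutually exclusive exons are clusters of internal exons of which exactly one
is included in any mature transcript. Because the alternatives encode the
same structural part of the protein, they tend to share three measurable
features: similar length, compatible splice sites and reading frames, and
sequence homology. `mxefinder` turns these constraints into a search: for
every annotated ("query") exon it scans the surrounding introns — or,
optionally, all introns and the up/downstream regions of the gene — for
intervals that could replace the query exon in the transcript.

## The algorithm

For an internal query exon of DNA length `L_q` flanked by introns with donor
`d` and acceptor `a`:

1. **Splice compatibility.** Candidate starts lie immediately after an
   acceptor dinucleotide compatible with `d` (AG for `d` ∈ {GT, GC, GG}; AC
   for `d` = AT); candidate ends lie at a donor dinucleotide compatible with
   `a` (GT/GC/GG for AG; AT for AC). Only the patterns GT—AG, GC—AG, GG—AG
   and AT—AC are admissible. First-exon candidates are anchored at an ATG
   start codon instead, last-exon candidates at a following stop codon.
2. **Frame and length.** A candidate of length `L_c` is kept iff
   `L_c ≡ L_q (mod 3)` and `|L_c − L_q| ≤ 3·Δ`, with Δ the *allowed length
   difference* in amino acids (default 20 aa). Candidates inherit the
   query's phase, so split codons in the query map to split codons in the
   candidate.
3. **Translation.** Candidates are translated in the query's reading frame
   (split codons completed from the flanking constitutive exons); any
   in-frame stop codon rejects the candidate.
4. **Homology.** Each translation is aligned globally to the query exon
   translation with the Gotoh affine-gap algorithm (Blosum62; a gap run of
   length ℓ costs `−10 − 2(ℓ−1)`). The score is divided by the query's
   self-alignment score, giving a relative score in (−∞, 1]; candidates
   below the *minimal score* (default 0.15) are rejected.
5. **Overlap resolution.** Among overlapping accepted candidates the
   highest-scoring (then longest, then leftmost) are retained. The query
   exon plus its surviving candidates form a cluster.

Optionally the search recurses (up to three rounds) with the found
candidates as queries, which recovers divergent cluster members. Clusters
are classified by query position — internal (candidate MXE cluster), first
exon (multiple-promoter-like) or last exon (multiple-poly(A)-like) — and
parallel ordered candidate groups across consecutive query exons are
re-labelled `group_pattern`: they usually betray tandem gene duplications or
*trans*-spliced exon groups rather than true MXEs.

A `screen` mode applies the search to every transcript of a GFF3
annotation, extracts annotation-defined MXE clusters (each transcript of
the gene contains exactly one member, ≥ 2 members, neighbouring, flanked by
further exons), scans neighbouring exon pairs for shared MXE features, and
reports exact-border sensitivity/specificity against the annotation.

## Worked example

Generate a synthetic gene with two identical copies of its second exon
implanted into introns, then search it:

```sh
mxefinder simulate --seed 5 --architecture implant --divergence 0.0 -o fix
mxefinder search fix/genome.fasta fix/annotation.gff3 -o out
cat out/report.txt
```

```
# transcript t5 (gene g5, 4 exons, strand +)
  cluster at exon 1 [566-656] (internal_mxe, 3 members)
    candidate [739-829] score 100.0% depth 0
      query     QSFGKGYEVSTDIPLQQQCYNWGIVECIQD
                ------------------------------
      candidate QSFGKGYEVSTDIPLQQQCYNWGIVECIQD
    candidate [960-1050] score 100.0% depth 0
      ...
```

The query exon at 566–656 gained two candidates with relative score 100.0%
— the implanted copies, recovered with exact borders (the ground truth is
in `fix/truth.tsv`). In the alignment block identities are drawn as dashes
and mismatches marked with `x`. Machine-readable results are written as
GFF3 (one feature per cluster member, with `cluster_id`, `relative_score`,
`recursion_depth` and `classification` attributes), as a lossless YAML
document, and as a TSV table. `mxefinder screen` writes the genome-scale
report, and `mxefinder compare` counts exact and overlapping borders
between two GFF3 exon sets.

All search parameters are exposed as flags (`--allowed-length-difference`,
`--min-score`, `--min-exon-length`, `--max-recursion-depth`,
`--search-all-introns`, `--search-updownstream`, `--region-size`,
`--start-codon-mode`, `--stop-codon-mode`).

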