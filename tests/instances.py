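"""Seeded random instance builders shared by the oracle-equivalence tests."""

import numpy as np

from mxefinder.model import GenomicSequence, derive_gene_structure
from mxefinder.search import SearchParams

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_cds(rng: np.random.Generator, n_codons: int, start_atg=True) -> str:
    body = "".join(_CODONS[rng.integers(len(_CODONS))] for _ in range(n_codons))
    return ("ATG" + body[3:]) if start_atg else body


def random_bg(rng: np.random.Generator, n: int, with_n=False) -> str:
    s = "".join("ACGT"[rng.integers(4)] for _ in range(n))
    if with_n and n > 10:
        k = int(rng.integers(1, 4))
        pos = rng.integers(0, n, size=k)
        s = "".join("N" if i in set(pos.tolist()) else c for i, c in enumerate(s))
    return s


def make_enum_case(rng: np.random.Generator):
    """A random (gene, query exon, region, params) enumeration instance.

    Returns (gene, query_index, region_bounds, params, anchors, targets)
    where targets are the dinucleotide sets the brute-force oracle needs.
    """
    from mxefinder.splice import acceptor_targets, donor_targets

    kind = ["internal", "internal", "internal", "first", "last"][rng.integers(5)]
    ald = int([0, 2, 5, 20][rng.integers(4)])
    margin = int([0, 4, 10][rng.integers(3)])
    region_len = int(rng.integers(50, 2001))

    # random split points give split codons at exon borders
    total = int(rng.integers(24, 90))
    cds = random_cds(rng, total)
    cut1 = int(rng.integers(9, len(cds) - 18))
    cut2 = int(rng.integers(cut1 + 9, len(cds) - 9))
    bodies = [cds[:cut1], cds[cut1:cut2], cds[cut2:]]

    donor1 = ["GT", "GC", "GG", "AT", "CA"][rng.integers(5)]
    acc1 = {"GT": "AG", "GC": "AG", "GG": "AG", "AT": "AC", "CA": "AG"}[donor1]
    donor2 = "GT"
    acc2 = ["AG", "AC", "TT"][rng.integers(3)]

    filler1 = random_bg(rng, int(rng.integers(16, 60)))
    filler2 = random_bg(rng, region_len - 4, with_n=rng.random() < 0.3)
    intron1 = donor1 + filler1 + acc1
    intron2 = donor2 + filler2 + acc2

    flank = random_bg(rng, 30)
    pieces = [flank, bodies[0], intron1, bodies[1], intron2, bodies[2], "TAA", flank]
    coords = []
    pos = len(flank)
    for body, intr in ((bodies[0], intron1), (bodies[1], intron2), (bodies[2], None)):
        coords.append((pos, pos + len(body)))
        pos += len(body)
        if intr:
            pos += len(intr)
    seq = GenomicSequence("case", "".join(pieces))
    gene = derive_gene_structure(coords, seq)
    params = SearchParams(
        allowed_length_difference=ald,
        min_exon_length=0,
        min_new_intron_length=margin,
        search_with_start_codon="on",
        search_with_stop_codon="on",
    )

    if kind == "internal":
        qi = 1
        region_bounds = (gene.introns[1].start, gene.introns[1].end)
        anchors = ("splice", "splice")
        targets = (acceptor_targets(donor1), donor_targets(acc2))
    elif kind == "first":
        qi = 0
        region_bounds = (gene.introns[0].start, gene.introns[0].end)
        anchors = ("atg", "splice")
        targets = (None, donor_targets(gene.introns[0].acceptor))
    else:
        qi = 2
        region_bounds = (gene.introns[1].start, gene.introns[1].end)
        anchors = ("splice", "stop")
        targets = (acceptor_targets(gene.introns[1].donor), None)
    return gene, qi, region_bounds, params, anchors, targets
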