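"""Coordinate model: sequences, exons, introns and derived gene structures.

All coordinates are 0-based, half-open, on the forward-normalized gene axis:
minus-strand transcripts are reverse-complemented at load time so that every
downstream computation is strand-free.  Phases follow the GFF3 CDS phase
convention (number of nucleotides preceding the first complete codon of the
exon).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .errors import FormatError, StructureError

NUCLEOTIDES = frozenset("ACGTN")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {TAA, TAG, TGA}
START_CODON = "ATG"

_CODON_TABLE = dict(standard_dna_table.forward_table)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(dna: str) -> str:
    """Translate complete codons with the standard code.

    Stop codons become '*'; codons containing N (or any ambiguity) become
    'X'.  A trailing partial codon is ignored.
    """
    aa = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        if codon in _CODON_TABLE:
            aa.append(_CODON_TABLE[codon])
        elif codon in STOP_CODONS:
            aa.append("*")
        else:
            aa.append("X")
    return "".join(aa)


@dataclass(frozen=True)
class GenomicSequence:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - NUCLEOTIDES
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues) if c in bad
            )
            raise FormatError(
                f"sequence {self.id!r}: illegal character {self.residues[pos]!r} "
                f"at position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExonLocus:
    """One coding exon on the forward-normalized gene axis.

    ``start_phase`` counts the nucleotides of a split codon that precede the
    exon's first complete codon (GFF3 phase); ``end_phase`` counts those that
    follow its last complete codon.  ``aa_length`` is the number of codons
    the exon spans after completing split codons with flanking nucleotides.
    """

    start: int
    end: int
    index: int
    is_first: bool
    is_last: bool
    start_phase: int
    end_phase: int
    aa_length: int

    def __post_init__(self):
        if self.end <= self.start:
            raise StructureError(f"exon {self.index}: end {self.end} <= start {self.start}")
        if (self.length - self.start_phase) % 3 != self.end_phase:
            raise StructureError(
                f"exon {self.index}: phase algebra violated "
                f"(len={self.length}, start_phase={self.start_phase}, "
                f"end_phase={self.end_phase})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def kind(self) -> str:
        if self.is_first:
            return "first"
        if self.is_last:
            return "last"
        return "internal"

    @property
    def upstream_completion_length(self) -> int:
        """Nucleotides the previous exon contributes to the split start codon."""
        return (3 - self.start_phase) % 3

    @property
    def downstream_completion_length(self) -> int:
        """Nucleotides the next exon contributes to the split end codon."""
        return (3 - self.end_phase) % 3 if self.end_phase else 0


@dataclass(frozen=True)
class IntronLocus:
    start: int
    end: int
    donor: str
    acceptor: str
    flank_upstream_exon: int
    flank_downstream_exon: int

    def __post_init__(self):
        if self.end - self.start < 4:
            raise StructureError(
                f"intron ({self.start}, {self.end}) shorter than 4 nt"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneStructure:
    """A transcript's ordered exons and introns on a normalized sequence.

    ``sequence`` is already strand-normalized: for minus-strand transcripts it
    is the reverse complement of the chromosome and all coordinates are
    flipped, with ``strand`` recording the original orientation for output.
    """

    sequence: GenomicSequence
    transcript_id: str
    gene_id: str
    exons: list[ExonLocus]
    introns: list[IntronLocus]
    protein: str
    starts_with_met: bool
    followed_by_stop: bool
    strand: str = "+"

    @property
    def cds(self) -> str:
        return "".join(self.sequence.residues[e.start : e.end] for e in self.exons)

    def exon_dna(self, index: int) -> str:
        e = self.exons[index]
        return self.sequence.residues[e.start : e.end]

    def upstream_completion(self, index: int) -> str:
        """Split-codon completion nucleotides taken from the previous exon."""
        e = self.exons[index]
        k = e.upstream_completion_length
        if k == 0:
            return ""
        prev = self.exons[index - 1]
        return self.sequence.residues[prev.end - k : prev.end]

    def downstream_completion(self, index: int) -> str:
        """Split-codon completion nucleotides taken from the next exon."""
        e = self.exons[index]
        k = e.downstream_completion_length
        if k == 0:
            return ""
        nxt = self.exons[index + 1]
        return self.sequence.residues[nxt.start : nxt.start + k]

    def exon_protein(self, index: int) -> str:
        """Translation of one exon with split codons completed from flanks."""
        return translate_cds(
            self.upstream_completion(index)
            + self.exon_dna(index)
            + self.downstream_completion(index)
        )


def _exon_phases(lengths: list[int]) -> list[tuple[int, int]]:
    """(start_phase, end_phase) per exon under the GFF3 phase convention."""
    phases = []
    cum = 0
    for n in lengths:
        start_phase = (3 - cum % 3) % 3
        end_phase = (n - start_phase) % 3
        phases.append((start_phase, end_phase))
        cum += n
    return phases


def derive_gene_structure(
    exon_coords: list[tuple[int, int]],
    sequence: GenomicSequence,
    transcript_id: str = "t1",
    gene_id: str = "g1",
    strand: str = "+",
    allow_partial: bool = False,
) -> GeneStructure:
    """Build a validated GeneStructure from exon intervals on a sequence.

    Derives introns with their splice dinucleotides, GFF3 phases, the
    translated protein, and the start/stop context flags.  Raises
    StructureError for overlapping exons, introns shorter than 4 nt, or an
    internal stop codon in the translation (unless ``allow_partial``).
    """
    if not exon_coords:
        raise StructureError(f"{transcript_id}: no exons")
    coords = sorted(exon_coords)
    for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
        if s2 < e1:
            raise StructureError(
                f"{transcript_id}: exons ({s1},{e1}) and ({s2},{e2}) overlap"
            )
    if coords[0][0] < 0 or coords[-1][1] > sequence.length:
        raise StructureError(f"{transcript_id}: exon outside sequence bounds")

    lengths = [e - s for s, e in coords]
    phases = _exon_phases(lengths)
    n = len(coords)
    exons = [
        ExonLocus(
            start=s,
            end=e,
            index=i,
            is_first=(i == 0),
            is_last=(i == n - 1),
            start_phase=phases[i][0],
            end_phase=phases[i][1],
            aa_length=(
                lengths[i]
                + (3 - phases[i][0]) % 3
                + ((3 - phases[i][1]) % 3 if phases[i][1] else 0)
            )
            // 3,
        )
        for i, (s, e) in enumerate(coords)
    ]

    res = sequence.residues
    introns = [
        IntronLocus(
            start=a.end,
            end=b.start,
            donor=res[a.end : a.end + 2],
            acceptor=res[b.start - 2 : b.start],
            flank_upstream_exon=a.index,
            flank_downstream_exon=b.index,
        )
        for a, b in zip(exons, exons[1:])
    ]

    cds = "".join(res[s:e] for s, e in coords)
    protein = translate_cds(cds)
    if "*" in protein and not allow_partial:
        raise StructureError(
            f"{transcript_id}: internal stop codon in translation "
            f"at aa position {protein.index('*') + 1}"
        )
    end = coords[-1][1]
    followed_by_stop = len(cds) % 3 == 0 and res[end : end + 3] in STOP_CODONS
    return GeneStructure(
        sequence=sequence,
        transcript_id=transcript_id,
        gene_id=gene_id,
        exons=exons,
        introns=introns,
        protein=protein,
        starts_with_met=protein.startswith("M"),
        followed_by_stop=followed_by_stop,
        strand=strand,
    )
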