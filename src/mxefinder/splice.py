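"""Splice-site compatibility, reading-frame rules and in-frame translation.

Candidate exons must introduce introns following one of the four splice
patterns GT---AG, GC---AG, GG---AG or AT---AC.  The donor of the intron in
front of the query exon fixes which acceptor dinucleotides may precede a
candidate, and the acceptor of the intron behind the query exon fixes which
donor dinucleotides may follow it; AT pairs only with AC.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import START_CODON, STOP_CODONS, translate_cds

#: Donors of the canonical patterns, all pairing with the acceptor AG.
CANONICAL_DONORS = frozenset({"GT", "GC", "GG"})
#: The non-canonical AT---AC pattern.
AT_DONOR = "AT"
AC_ACCEPTOR = "AC"
AG_ACCEPTOR = "AG"

#: All representable (donor, acceptor) splice patterns.
SPLICE_PATTERNS = frozenset(
    {("GT", "AG"), ("GC", "AG"), ("GG", "AG"), ("AT", "AC")}
)


def acceptor_targets(upstream_intron_donor: str) -> frozenset[str]:
    """Acceptor dinucleotides that may end the intron preceding a candidate.

    An empty set signals a non-canonical donor on the annotated upstream
    intron; the query exon is then skipped.
    """
    if upstream_intron_donor in CANONICAL_DONORS:
        return frozenset({AG_ACCEPTOR})
    if upstream_intron_donor == AT_DONOR:
        return frozenset({AC_ACCEPTOR})
    return frozenset()


def donor_targets(downstream_intron_acceptor: str) -> frozenset[str]:
    """Donor dinucleotides that may start the intron following a candidate."""
    if downstream_intron_acceptor == AG_ACCEPTOR:
        return frozenset(CANONICAL_DONORS)
    if downstream_intron_acceptor == AC_ACCEPTOR:
        return frozenset({AT_DONOR})
    return frozenset()


@dataclass(frozen=True)
class FrameContext:
    """Length/frame compatibility context of one query exon.

    ``allowed_length_difference`` is in amino acids (default 20), so the
    candidate may differ from the query by at most 3x that many nucleotides,
    and only in whole codons.
    """

    query_dna_length: int
    query_aa_length: int
    start_phase: int
    end_phase: int
    allowed_length_difference: int = 20

    def __post_init__(self):
        if self.allowed_length_difference < 0:
            raise ValueError("allowed_length_difference must be >= 0")
        if self.query_dna_length < 3:
            raise ValueError("query_dna_length must be >= 3")


def is_frame_compatible(ctx: FrameContext, candidate_dna_length: int) -> bool:
    """True iff the candidate length preserves frame and the length window.

    Because a candidate inherits the query's start phase, a mod-3-equal
    length forces an equal end phase, so split codons in the query exon
    automatically map to split codons in the candidate.
    """
    diff = candidate_dna_length - ctx.query_dna_length
    return diff % 3 == 0 and abs(diff) <= 3 * ctx.allowed_length_difference


def translate_in_frame(
    dna: str,
    start_phase: int,
    upstream_completion: str = "",
    downstream_completion: str = "",
) -> str:
    """Translate an exon body in the query's frame, completing split codons.

    The completion nucleotides come from the flanking constitutive exons and
    are identical for the query and every candidate of its cluster.  Codons
    containing N translate to 'X'; in-frame stops appear as '*' and the
    caller rejects such candidates.
    """
    expect = (3 - start_phase) % 3
    if len(upstream_completion) != expect:
        raise ValueError(
            f"start_phase {start_phase} requires a {expect}-nt upstream "
            f"completion, got {len(upstream_completion)} nt"
        )
    return translate_cds(upstream_completion + dna + downstream_completion)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_start(codon: str) -> bool:
    return codon == START_CODON
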