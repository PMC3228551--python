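"""Enumeration of candidate exon intervals inside search regions.

A candidate is the sequence between a compatible acceptor dinucleotide
(start side) and a compatible donor dinucleotide (end side) inside one
region — an intron's interior or an up/downstream window.  Terminal query
exons are anchored differently: first-exon candidates start at ATG,
last-exon candidates end immediately before a stop codon.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import StructureError
from .model import GeneStructure, STOP_CODONS, START_CODON
from .splice import FrameContext, acceptor_targets, donor_targets, is_frame_compatible

if TYPE_CHECKING:  # pragma: no cover
    from .search import SearchParams

REGION_ROLES = (
    "upstream_intron",
    "downstream_intron",
    "other_intron",
    "upstream_region",
    "downstream_region",
)


@dataclass(frozen=True)
class SearchRegion:
    """A contiguous stretch of searchable sequence (genomic coordinates)."""

    start: int
    end: int
    role: str

    def __post_init__(self):
        if self.end <= self.start:
            raise StructureError(f"empty search region ({self.start}, {self.end})")
        if self.role not in REGION_ROLES:
            raise ValueError(f"unknown region role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateInterval:
    """A candidate exon interval with its anchoring evidence.

    ``acceptor_pos``/``donor_pos`` are the genomic positions of the bounding
    dinucleotides; they are None for ATG-anchored starts and stop-anchored
    ends of terminal-exon candidates.
    """

    start: int
    end: int
    query_exon_index: int
    source_region: SearchRegion | None
    acceptor_pos: int | None
    donor_pos: int | None

    def __post_init__(self):
        if self.end - self.start < 3:
            raise StructureError("candidate shorter than one codon")

    @property
    def length(self) -> int:
        return self.end - self.start


def find_acceptor_sites(
    residues: str,
    region: SearchRegion,
    targets: frozenset[str] | set[str],
    min_new_intron_length: int = 0,
) -> list[int]:
    """Candidate start positions after target acceptor dinucleotides.

    Every occurrence of a target dinucleotide at genomic position p yields a
    candidate start p + 2 (overlapping occurrences included).  Starts closer
    than ``min_new_intron_length`` to the region's 5' boundary are dropped,
    since the implied upstream intron would be too short.
    """
    lo = max(region.start, region.start + min_new_intron_length - 2)
    starts = []
    for p in range(lo, region.end - 1):
        if residues[p : p + 2] in targets:
            starts.append(p + 2)
    return starts


def find_donor_sites(
    residues: str,
    region: SearchRegion,
    targets: frozenset[str] | set[str],
    min_new_intron_length: int = 0,
) -> list[int]:
    """Candidate end positions at target donor dinucleotides (mirror rule)."""
    hi = min(region.end - 1, region.end - min_new_intron_length + 1)
    ends = []
    for p in range(region.start, hi):
        if residues[p : p + 2] in targets:
            ends.append(p)
    return ends


def _find_atg_starts(residues: str, region: SearchRegion) -> list[int]:
    return [
        p
        for p in range(region.start, region.end - 2)
        if residues[p : p + 3] == START_CODON
    ]


def _find_stop_ends(residues: str, region: SearchRegion) -> list[int]:
    """Ends e such that residues[e:e+3] is a stop codon within the region."""
    return [
        e
        for e in range(region.start, region.end - 2)
        if residues[e : e + 3] in STOP_CODONS
    ]


def _pair_sites(
    gene: GeneStructure,
    query_exon_index: int,
    region: SearchRegion,
    starts: list[int],
    ends: list[int],
    ctx: FrameContext,
    start_anchored: bool,
    end_anchored: bool,
) -> list[CandidateInterval]:
    """Cross compatible (start, end) pairs into candidate intervals.

    Keeps pairs with end > start, frame/length compatibility, and an
    N-free body; list sorted by (start, end).
    """
    res = gene.sequence.residues
    qlen = ctx.query_dna_length
    span = 3 * ctx.allowed_length_difference
    ends = sorted(ends)
    out = []
    for s in sorted(starts):
        lo = bisect_left(ends, max(s + 3, s + qlen - span))
        hi = bisect_right(ends, s + qlen + span)
        for e in ends[lo:hi]:
            if not is_frame_compatible(ctx, e - s):
                continue
            if "N" in res[s:e]:
                continue
            out.append(
                CandidateInterval(
                    start=s,
                    end=e,
                    query_exon_index=query_exon_index,
                    source_region=region,
                    acceptor_pos=s - 2 if start_anchored else None,
                    donor_pos=e if end_anchored else None,
                )
            )
    out.sort(key=lambda c: (c.start, c.end))
    return out


def _frame_context(gene: GeneStructure, exon_index: int, params: "SearchParams") -> FrameContext:
    e = gene.exons[exon_index]
    return FrameContext(
        query_dna_length=e.length,
        query_aa_length=e.aa_length,
        start_phase=e.start_phase,
        end_phase=e.end_phase,
        allowed_length_difference=params.allowed_length_difference,
    )


def enumerate_with_context(
    gene: GeneStructure,
    query_exon_index: int,
    region: SearchRegion,
    params: "SearchParams",
    ctx: FrameContext,
    start_anchor: str,
    end_anchor: str,
) -> list[CandidateInterval]:
    """Anchored enumeration with an explicit frame context.

    ``start_anchor`` is "splice" (acceptor-target dinucleotides derived from
    the donor of the intron in front of the query exon) or "atg";
    ``end_anchor`` is "splice" (donor targets from the acceptor of the
    intron behind the query exon) or "stop".  The recursive search reuses
    this with the frame context of a previously found candidate.
    """
    res = gene.sequence.residues
    if start_anchor == "splice":
        acc = acceptor_targets(gene.introns[query_exon_index - 1].donor)
        if not acc:
            return []
        starts = find_acceptor_sites(res, region, acc, params.min_new_intron_length)
    elif start_anchor == "atg":
        starts = _find_atg_starts(res, region)
    else:
        raise ValueError(f"unknown start anchor {start_anchor!r}")
    if end_anchor == "splice":
        don = donor_targets(gene.introns[query_exon_index].acceptor)
        if not don:
            return []
        ends = find_donor_sites(res, region, don, params.min_new_intron_length)
    elif end_anchor == "stop":
        ends = _find_stop_ends(res, region)
    else:
        raise ValueError(f"unknown end anchor {end_anchor!r}")
    return _pair_sites(
        gene,
        query_exon_index,
        region,
        starts,
        ends,
        ctx,
        start_anchor == "splice",
        end_anchor == "splice",
    )


def enumerate_candidates(
    gene: GeneStructure,
    query_exon_index: int,
    region: SearchRegion,
    params: "SearchParams",
) -> list[CandidateInterval]:
    """All splice-anchored candidate intervals for an internal query exon.

    The acceptor targets derive from the donor of the intron in front of the
    query exon, the donor targets from the acceptor of the intron behind it;
    an empty target set on either side yields no candidates (the caller
    logs the skip).  Query exons shorter than ``min_exon_length`` aa are not
    searched.
    """
    exon = gene.exons[query_exon_index]
    if exon.aa_length < params.min_exon_length:
        return []
    if exon.is_first or exon.is_last:
        raise StructureError(
            "enumerate_candidates handles internal exons; use the "
            "terminal-exon variants for first/last exons"
        )
    ctx = _frame_context(gene, query_exon_index, params)
    return enumerate_with_context(
        gene, query_exon_index, region, params, ctx, "splice", "splice"
    )


def enumerate_first_exon_candidates(
    gene: GeneStructure,
    region: SearchRegion,
    params: "SearchParams",
) -> list[CandidateInterval]:
    """ATG-anchored candidates for the first exon.

    Starts are anchored at ATG occurrences (no implied upstream intron, so
    no 5' margin); ends at donor-target dinucleotides compatible with the
    acceptor of the first intron.
    """
    exon = gene.exons[0]
    if exon.aa_length < params.min_exon_length:
        return []
    if not gene.introns:
        return []
    ctx = _frame_context(gene, 0, params)
    return enumerate_with_context(gene, 0, region, params, ctx, "atg", "splice")


def enumerate_last_exon_candidates(
    gene: GeneStructure,
    region: SearchRegion,
    params: "SearchParams",
) -> list[CandidateInterval]:
    """Stop-anchored candidates for the last exon.

    Starts at acceptor-target sites compatible with the donor of the last
    intron; the interval end is chosen so that the next three nucleotides
    form a stop codon (in frame by construction, since the candidate length
    is a codon-multiple offset of the query length).
    """
    last = len(gene.exons) - 1
    exon = gene.exons[last]
    if exon.aa_length < params.min_exon_length:
        return []
    if not gene.introns:
        return []
    ctx = _frame_context(gene, last, params)
    return enumerate_with_context(gene, last, region, params, ctx, "splice", "stop")
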