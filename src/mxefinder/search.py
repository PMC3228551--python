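"""Per-exon and per-transcript MXE search, recursion and classification.

For every eligible query exon the surrounding introns (or, optionally, all
introns and up/downstream windows) are scanned for candidates, which are
pooled, scored, thresholded and overlap-resolved into a cluster.  Clusters
are classified by the position of the query exon: alternatives of internal
exons are candidate mutually exclusive exons, alternatives of terminal
exons resemble multiple promoters or multiple poly(A) sites, and parallel
ordered candidate groups across consecutive query exons indicate tandem
gene duplications or trans-spliced exon groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .candidates import (
    CandidateInterval,
    SearchRegion,
    _frame_context,
    enumerate_with_context,
)
from .model import GeneStructure
from .scoring import (
    AlignmentParams,
    ScoredCandidate,
    overlaps,
    resolve_overlaps,
    score_candidates,
    self_score,
    gotoh_align,
    SCORE_EPS,
)
from .splice import FrameContext, acceptor_targets, donor_targets, translate_in_frame

CLASSIFICATIONS = (
    "internal_mxe",
    "multiple_promoter_like",
    "multiple_polyA_like",
    "group_pattern",
)


@dataclass
class SearchParams:
    """Every user-tunable search parameter with its default.

    Units: ``allowed_length_difference`` and ``min_exon_length`` in amino
    acids, ``region_size`` and ``min_new_intron_length`` in nucleotides,
    ``min_score`` as a fraction of the query self-score.
    """

    allowed_length_difference: int = 20
    min_score: float = 0.15
    min_exon_length: int = 15
    max_recursion_depth: int = 0
    search_all_introns: bool = False
    search_updownstream: bool = False
    region_size: int = 10_000
    search_with_start_codon: str = "auto"  # auto|on|off
    search_with_stop_codon: str = "auto"
    min_new_intron_length: int = 4
    group_min_consecutive: int = 2
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    seed: int = 0  # used only by fixture generation

    def __post_init__(self):
        if not 0 <= self.max_recursion_depth <= 3:
            raise ValueError("max_recursion_depth must be in 0..3")
        for name in (
            "allowed_length_difference",
            "min_score",
            "min_exon_length",
            "region_size",
            "min_new_intron_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("search_with_start_codon", "search_with_stop_codon"):
            if getattr(self, name) not in ("auto", "on", "off"):
                raise ValueError(f"{name} must be auto, on or off")


@dataclass
class ExonCluster:
    """A query exon plus its accepted mutually-exclusive candidates.

    ``members[0]`` is the annotated query exon itself (relative score 1.0);
    all members are pairwise non-overlapping.
    """

    query_exon_index: int
    members: list[ScoredCandidate]
    classification: str = "internal_mxe"
    recursion_rounds_used: int = 0

    @property
    def candidates(self) -> list[ScoredCandidate]:
        return self.members[1:]

    @property
    def is_trivial(self) -> bool:
        return len(self.members) <= 1


@dataclass
class SearchResult:
    gene: GeneStructure
    clusters: list[ExonCluster]
    params: SearchParams
    log: list[dict] = field(default_factory=list)


def _query_member(gene: GeneStructure, exon_index: int, params: SearchParams) -> ScoredCandidate:
    exon = gene.exons[exon_index]
    aa = gene.exon_protein(exon_index)
    s = self_score(aa, params.alignment)
    return ScoredCandidate(
        interval=CandidateInterval(
            start=exon.start,
            end=exon.end,
            query_exon_index=exon_index,
            source_region=None,
            acceptor_pos=None,
            donor_pos=None,
        ),
        translation=aa,
        raw_score=s,
        self_score=s,
        relative_score=1.0,
        accepted=True,
        alignment=(aa, aa),
        is_query=True,
    )


def _start_mode_on(gene: GeneStructure, params: SearchParams) -> bool:
    if params.search_with_start_codon == "auto":
        return gene.starts_with_met
    return params.search_with_start_codon == "on"


def _stop_mode_on(gene: GeneStructure, params: SearchParams) -> bool:
    if params.search_with_stop_codon == "auto":
        return gene.followed_by_stop
    return params.search_with_stop_codon == "on"


def regions_for_exon(
    gene: GeneStructure, exon_index: int, params: SearchParams
) -> list[SearchRegion]:
    """Search regions for one query exon under the current scope settings.

    Default scope is the surrounding intron(s); ``search_all_introns``
    widens it to every intron.  Up/downstream windows of ``region_size`` nt
    are added for terminal exons when ``search_updownstream`` is set, and
    for every exon when ``search_all_introns`` is also set (the scope used
    to recognize tandem gene arrays).
    """
    exon = gene.exons[exon_index]
    regions: list[SearchRegion] = []

    def intron_role(j: int) -> str:
        if j == exon_index - 1:
            return "upstream_intron"
        if j == exon_index:
            return "downstream_intron"
        return "other_intron"

    if params.search_all_introns:
        intron_ids = range(len(gene.introns))
    else:
        intron_ids = [
            j for j in (exon_index - 1, exon_index) if 0 <= j < len(gene.introns)
        ]
    for j in intron_ids:
        intr = gene.introns[j]
        if intr.length >= 3:
            regions.append(SearchRegion(intr.start, intr.end, intron_role(j)))

    windows_for_all = params.search_updownstream and params.search_all_introns
    if params.search_updownstream and (exon.is_first or windows_for_all):
        first = gene.exons[0]
        lo = max(0, first.start - params.region_size)
        if first.start - lo >= 3:
            regions.append(SearchRegion(lo, first.start, "upstream_region"))
    if params.search_updownstream and (exon.is_last or windows_for_all):
        last = gene.exons[-1]
        hi = min(gene.sequence.length, last.end + params.region_size)
        if hi - last.end >= 3:
            regions.append(SearchRegion(last.end, hi, "downstream_region"))
    return regions


def _anchors_for_exon(
    gene: GeneStructure, exon_index: int, params: SearchParams
) -> tuple[str, str] | None:
    """(start_anchor, end_anchor) for a query exon, or None to skip it."""
    exon = gene.exons[exon_index]
    if exon.is_first and exon.is_last:
        if _start_mode_on(gene, params) and _stop_mode_on(gene, params):
            return ("atg", "stop")
        return None
    if exon.is_first:
        return ("atg", "splice") if _start_mode_on(gene, params) else None
    if exon.is_last:
        return ("splice", "stop") if _stop_mode_on(gene, params) else None
    return ("splice", "splice")


def _enumerate_pool(
    gene: GeneStructure,
    exon_index: int,
    regions: list[SearchRegion],
    params: SearchParams,
    ctx: FrameContext,
    anchors: tuple[str, str],
    log: list[dict],
) -> list[CandidateInterval]:
    exon = gene.exons[exon_index]
    if anchors[0] == "splice":
        donor = gene.introns[exon_index - 1].donor
        if not acceptor_targets(donor):
            log.append(
                {
                    "exon": exon_index,
                    "event": "skip",
                    "reason": f"non-canonical upstream intron donor {donor!r}",
                }
            )
            return []
    if anchors[1] == "splice":
        acc = gene.introns[exon_index].acceptor
        if not donor_targets(acc):
            log.append(
                {
                    "exon": exon_index,
                    "event": "skip",
                    "reason": f"non-canonical downstream intron acceptor {acc!r}",
                }
            )
            return []
    pool: list[CandidateInterval] = []
    for region in regions:
        for cand in enumerate_with_context(
            gene, exon_index, region, params, ctx, anchors[0], anchors[1]
        ):
            # a query exon's own locus is never a candidate for itself
            if cand.start == exon.start and cand.end == exon.end:
                continue
            pool.append(cand)
    return pool


def search_exon(
    gene: GeneStructure,
    exon_index: int,
    params: SearchParams,
    log: list[dict] | None = None,
) -> ExonCluster:
    """Assemble the cluster of accepted candidates for one query exon."""
    log = log if log is not None else []
    cluster = ExonCluster(
        query_exon_index=exon_index,
        members=[_query_member(gene, exon_index, params)],
    )
    exon = gene.exons[exon_index]
    if exon.aa_length < params.min_exon_length:
        log.append(
            {
                "exon": exon_index,
                "event": "skip",
                "reason": f"query exon shorter than {params.min_exon_length} aa",
            }
        )
        return cluster
    anchors = _anchors_for_exon(gene, exon_index, params)
    if anchors is None:
        log.append(
            {
                "exon": exon_index,
                "event": "skip",
                "reason": "terminal exon with start/stop-codon search disabled",
            }
        )
        return cluster
    regions = regions_for_exon(gene, exon_index, params)
    ctx = _frame_context(gene, exon_index, params)
    pool = _enumerate_pool(gene, exon_index, regions, params, ctx, anchors, log)
    scored = score_candidates(exon, pool, gene, params)
    cluster.members.extend(resolve_overlaps(scored))
    cluster.classification = classify_cluster(cluster, gene)
    return cluster


def recursive_expand(
    gene: GeneStructure, cluster: ExonCluster, params: SearchParams
) -> ExonCluster:
    """Repeat the search with found candidates as queries (bounded rounds).

    Each round uses every not-yet-queried member as a query over the same
    regions as the top-level run.  New accepted candidates are deduplicated
    by exact genomic interval and merged by overlap resolution in which
    existing members always win; previously accepted members are never
    removed, so the member set grows monotonically with depth.
    """
    if params.max_recursion_depth < 1 or cluster.is_trivial:
        return cluster
    exon_index = cluster.query_exon_index
    exon = gene.exons[exon_index]
    anchors = _anchors_for_exon(gene, exon_index, params)
    if anchors is None:
        return cluster
    regions = regions_for_exon(gene, exon_index, params)
    up = gene.upstream_completion(exon_index)
    down = gene.downstream_completion(exon_index)

    queried = {(cluster.members[0].start, cluster.members[0].end)}
    rounds = 0
    scratch_log: list[dict] = []
    for _ in range(params.max_recursion_depth):
        frontier = [
            m for m in cluster.members if (m.start, m.end) not in queried
        ]
        if not frontier:
            break
        rounds += 1
        new: dict[tuple[int, int], ScoredCandidate] = {}
        existing = {(m.start, m.end) for m in cluster.members}
        for member in frontier:
            queried.add((member.start, member.end))
            q_aa = member.translation
            s_self = self_score(q_aa, params.alignment)
            if s_self <= 0:
                continue
            ctx = FrameContext(
                query_dna_length=member.length,
                query_aa_length=len(q_aa),
                start_phase=exon.start_phase,
                end_phase=(member.length - exon.start_phase) % 3,
                allowed_length_difference=params.allowed_length_difference,
            )
            pool = _enumerate_pool(
                gene, exon_index, regions, params, ctx, anchors, scratch_log
            )
            for cand in pool:
                key = (cand.start, cand.end)
                if key in existing or key in new:
                    continue
                body = gene.sequence.residues[cand.start : cand.end]
                aa = translate_in_frame(body, exon.start_phase, up, down)
                if "*" in aa or (aa and aa.count("X") * 2 > len(aa)):
                    continue
                raw, ga, gb = gotoh_align(aa, q_aa, params.alignment)
                rel = raw / s_self
                if rel < params.min_score - SCORE_EPS:
                    continue
                new[key] = ScoredCandidate(
                    interval=cand,
                    translation=aa,
                    raw_score=raw,
                    self_score=s_self,
                    relative_score=rel,
                    accepted=True,
                    alignment=(ga, gb),
                    depth=rounds,
                )
        if not new:
            break
        added = resolve_overlaps(list(new.values()))
        for cand in added:
            if all(not overlaps(cand, m) for m in cluster.members):
                cluster.members.append(cand)
    cluster.members[1:] = sorted(cluster.members[1:], key=lambda m: m.start)
    cluster.recursion_rounds_used = rounds
    return cluster


def classify_cluster(cluster: ExonCluster, gene: GeneStructure) -> str:
    """Position-based classification of a cluster's query exon."""
    exon = gene.exons[cluster.query_exon_index]
    if exon.is_first:
        return "multiple_promoter_like"
    if exon.is_last:
        return "multiple_polyA_like"
    return "internal_mxe"


def detect_group_pattern(result: SearchResult, params: SearchParams) -> SearchResult:
    """Flag parallel ordered candidate groups across consecutive query exons.

    When candidates of at least ``group_min_consecutive`` consecutive query
    exons can be chained in the same genomic order, at most ``region_size``
    nt apart, with no annotated exon of the transcript between consecutive
    chain members, the involved clusters most probably reflect a tandem
    gene duplication or a trans-spliced exon group and are re-labelled
    ``group_pattern``.  Requires a result produced with
    ``search_all_introns`` enabled.
    """
    if not params.search_all_introns:
        return result
    by_qi = {c.query_exon_index: c for c in result.clusters if not c.is_trivial}
    if not by_qi:
        return result
    exon_intervals = [(e.start, e.end) for e in result.gene.exons]

    def blocked(a: ScoredCandidate, b: ScoredCandidate) -> bool:
        for s, e in exon_intervals:
            if (s, e) in ((a.start, a.end), (b.start, b.end)):
                continue
            if s >= a.end and e <= b.start:
                return True
        return False

    def linkable(a: ScoredCandidate, b: ScoredCandidate) -> bool:
        return (
            b.start >= a.end
            and b.start - a.end <= params.region_size
            and not blocked(a, b)
        )

    # chain DP over candidates of consecutive query exons
    chain_len: dict[tuple[int, int, int], int] = {}
    flagged: set[int] = set()
    indices = sorted(by_qi)
    for qi in indices:
        for ci, cand in enumerate(by_qi[qi].candidates):
            best = 1
            if qi - 1 in by_qi:
                for pj, prev in enumerate(by_qi[qi - 1].candidates):
                    if linkable(prev, cand):
                        best = max(best, chain_len.get((qi - 1, pj, 0), 1) + 1)
            chain_len[(qi, ci, 0)] = best
    # walk back to flag all clusters on chains reaching the threshold
    for (qi, ci, _), ln in chain_len.items():
        if ln >= params.group_min_consecutive:
            q, cand = qi, by_qi[qi].candidates[ci]
            flagged.add(q)
            while q - 1 in by_qi:
                prevs = [
                    (pj, p)
                    for pj, p in enumerate(by_qi[q - 1].candidates)
                    if linkable(p, cand) and chain_len[(q - 1, pj, 0)] >= 1
                ]
                if not prevs:
                    break
                pj, cand = max(prevs, key=lambda t: chain_len[(q - 1, t[0], 0)])
                q -= 1
                flagged.add(q)
    for qi in flagged:
        by_qi[qi].classification = "group_pattern"
    return result


def search_transcript(
    gene: GeneStructure,
    params: SearchParams,
    known_exon_intervals: set[tuple[int, int]] | None = None,
) -> SearchResult:
    """Run the per-exon search over every exon of a transcript.

    ``known_exon_intervals`` (defaulting to the transcript's own exon
    intervals) marks candidates that coincide exactly with an annotated
    exon — in all-introns scope this is how trans-spliced groups surface.
    """
    log: list[dict] = []
    if known_exon_intervals is None:
        known_exon_intervals = {(e.start, e.end) for e in gene.exons}
    clusters: list[ExonCluster] = []
    for i in range(len(gene.exons)):
        cluster = search_exon(gene, i, params, log)
        if params.max_recursion_depth >= 1 and not cluster.is_trivial:
            cluster = recursive_expand(gene, cluster, params)
        for member in cluster.candidates:
            key = (member.start, member.end)
            if key in known_exon_intervals:
                member.matches_annotated_exon = next(
                    (
                        e.index
                        for e in gene.exons
                        if (e.start, e.end) == key
                    ),
                    -1,
                )
        if cluster.is_trivial:
            log.append(
                {"exon": i, "event": "no_candidates", "reason": "cluster of one"}
            )
        else:
            clusters.append(cluster)
    result = SearchResult(gene=gene, clusters=clusters, params=params, log=log)
    if params.search_all_introns:
        detect_group_pattern(result, params)
    return result
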