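"""Annotation-scale screening: run the search over every transcript,
extract annotation-defined MXE clusters, scan neighbouring exons for shared
MXE features, and compute agreement statistics.

An annotated cluster of mutually exclusive exons requires that each
transcript of the gene contains exactly one member, the cluster has at
least two members, the members are neighbouring exons, and the cluster is
surrounded by further exons; unflanked clusters are classified as multiple
promoters (first exons) or multiple poly(A) sites (last exons), and genes
whose members come in blocks of two or more exons per transcript are
flagged as group-type (likely trans-spliced) and excluded from the
sensitivity/specificity analysis.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .gene_io import read_fasta, read_gff3
from .model import GeneStructure
from .scoring import gotoh_align, self_score
from .search import SearchParams, search_transcript


@dataclass
class AnnotatedMxeCluster:
    """An annotation-defined cluster of mutually exclusive exon loci."""

    gene_id: str
    members: list[tuple[int, int]]
    flanked: bool
    terminal_side: str  # none|first|last
    group_type: bool = False


@dataclass
class ScreenReport:
    """Tallies of a whole-annotation screen; counts are reproducible from
    the per-record candidate table in ``records``."""

    n_genes: int
    n_transcripts: int
    n_exons: int
    predicted: dict
    annotated: dict
    matched_exact: int
    new_candidates: int
    overlap_only: int
    neighbour: dict
    sensitivity: dict
    specificity: dict
    records: pd.DataFrame
    skipped: list = field(default_factory=list)


def annotated_mxe_clusters(transcripts: list[GeneStructure]) -> list[AnnotatedMxeCluster]:
    """Annotation-defined MXE clusters among one gene's transcripts.

    Works on distinct exon intervals ordered along the gene axis: a maximal
    run of non-universal exons whose per-exon transcript sets partition the
    gene's transcripts is a cluster (group-type when the partition blocks
    hold two or more exons each).  Invariant under transcript order.
    """
    if not transcripts:
        return []
    gene_id = transcripts[0].gene_id
    all_tids = frozenset(t.transcript_id for t in transcripts)
    containing: dict[tuple[int, int], set[str]] = defaultdict(set)
    for t in transcripts:
        for e in t.exons:
            containing[(e.start, e.end)].add(t.transcript_id)
    intervals = sorted(containing)
    is_first_exon = {
        (t.exons[0].start, t.exons[0].end) for t in transcripts
    }
    is_last_exon = {
        (t.exons[-1].start, t.exons[-1].end) for t in transcripts
    }

    clusters: list[AnnotatedMxeCluster] = []
    run: list[tuple[int, int]] = []

    def close_run(run, before_exists, after_exists):
        if len(run) < 2:
            return
        groups: dict[frozenset, list[tuple[int, int]]] = defaultdict(list)
        for iv in run:
            groups[frozenset(containing[iv])].append(iv)
        tid_sets = list(groups)
        union = frozenset().union(*tid_sets)
        disjoint = sum(len(s) for s in tid_sets) == len(union)
        if union != all_tids or not disjoint or len(tid_sets) < 2:
            return
        sizes = {len(v) for v in groups.values()}
        if sizes == {1}:
            group_type = False
        elif all(n >= 2 for n in sizes):
            group_type = True
        else:
            return
        flanked = before_exists and after_exists
        if flanked:
            side = "none"
        elif all(iv in is_first_exon for iv in run) and not before_exists:
            side = "first"
        elif all(iv in is_last_exon for iv in run) and not after_exists:
            side = "last"
        else:
            side = "none"
        clusters.append(
            AnnotatedMxeCluster(
                gene_id=gene_id,
                members=sorted(run),
                flanked=flanked,
                terminal_side=side,
                group_type=group_type,
            )
        )

    for i, iv in enumerate(intervals):
        if containing[iv] == all_tids:
            if run:
                close_run(run, intervals[0] != run[0], True)
                run = []
        else:
            run.append(iv)
    if run:
        close_run(run, intervals[0] != run[0], run[-1] != intervals[-1])
    return clusters


def neighbour_similarity_scan(
    transcripts: list[GeneStructure], params: SearchParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Flag adjacent exon pairs sharing the MXE features.

    A pair is flagged iff both exons code for at least ``min_exon_length``
    aa, their lengths differ by at most ``allowed_length_difference`` aa in
    whole codons, they start in the same phase, and their alignment score
    relative to the upstream exon's self-score reaches ``min_score``.
    Exons are counted per transcript, not per gene.
    """
    params = params or SearchParams()
    rows = []
    flagged_exons: set[tuple[str, int]] = set()
    flagged_transcripts: set[str] = set()
    flagged_genes: set[str] = set()
    n_exons = 0
    for t in transcripts:
        n_exons += len(t.exons)
        for a, b in zip(t.exons, t.exons[1:]):
            if a.aa_length < params.min_exon_length or b.aa_length < params.min_exon_length:
                continue
            dna_diff = b.length - a.length
            if dna_diff % 3 != 0:
                continue
            if abs(dna_diff) > 3 * params.allowed_length_difference:
                continue
            if a.start_phase != b.start_phase:
                continue
            aa_a = t.exon_protein(a.index)
            aa_b = t.exon_protein(b.index)
            s_self = self_score(aa_a, params.alignment)
            if s_self <= 0:
                continue
            raw, _, _ = gotoh_align(aa_b, aa_a, params.alignment)
            rel = raw / s_self
            if rel < params.min_score - 1e-9:
                continue
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "transcript_id": t.transcript_id,
                    "exon_a": a.index,
                    "exon_b": b.index,
                    "relative_score": round(rel, 6),
                }
            )
            flagged_exons.update({(t.transcript_id, a.index), (t.transcript_id, b.index)})
            flagged_transcripts.add(t.transcript_id)
            flagged_genes.add(t.gene_id)
    table = pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "exon_a", "exon_b", "relative_score"]
    )
    counts = {
        "exons": len(flagged_exons),
        "transcripts": len(flagged_transcripts),
        "genes": len(flagged_genes),
        "total_exons": n_exons,
        "total_transcripts": len(transcripts),
        "total_genes": len({t.gene_id for t in transcripts}),
    }
    return table, counts


def evaluate_against_annotation(
    predictions: set | list,
    annotated: set | list,
    prediction_overlap_pool: set | list | None = None,
) -> tuple[dict, dict, pd.DataFrame]:
    """Exact-border agreement of predicted exon intervals with annotation.

    Items are (gene_id, start, end) keys.  Sensitivity is matched annotated
    exons over all annotated exons; specificity is matched predictions over
    all predictions.  Predictions overlapping an annotated exon without an
    exact match are listed separately in the table.
    """
    pred = set(predictions)
    ann = set(annotated)
    pool = set(prediction_overlap_pool) if prediction_overlap_pool else ann
    matched = pred & ann
    rows = []
    for g, s, e in sorted(pred):
        status = "exact" if (g, s, e) in matched else "new"
        if status == "new":
            for g2, s2, e2 in pool:
                if g2 == g and s < e2 and s2 < e and (s, e) != (s2, e2):
                    status = "overlap_only"
                    break
        rows.append({"gene_id": g, "start": s, "end": e, "status": status})
    table = pd.DataFrame(rows, columns=["gene_id", "start", "end", "status"])
    sensitivity = {
        "value": len(matched) / len(ann) if ann else float("nan"),
        "numerator": len(matched),
        "denominator": len(ann),
    }
    specificity = {
        "value": len(matched) / len(pred) if pred else float("nan"),
        "numerator": len(matched),
        "denominator": len(pred),
    }
    return sensitivity, specificity, table


def compare_exon_sets(set_a, set_b) -> tuple[int, int]:
    """Exact-border and >=1-bp-overlap counts of set_a intervals against set_b.

    Intervals are (start, end) pairs or (seqid, start, end) triples.
    """
    def norm(items):
        out = []
        for it in items:
            if len(it) == 2:
                out.append((None, it[0], it[1]))
            else:
                out.append(tuple(it))
        return out

    a, b = norm(set_a), norm(set_b)
    b_exact = set(b)
    exact = sum(1 for iv in a if iv in b_exact)
    overlap = sum(
        1
        for (ga, sa, ea) in a
        if any(gb == ga and sa < eb and sb < ea for (gb, sb, eb) in b)
    )
    return exact, overlap


def _screen_params(params: SearchParams | None) -> SearchParams:
    return params or SearchParams()


def screen_structures(
    transcripts: list[GeneStructure], params: SearchParams | None = None
) -> ScreenReport:
    """Core of the annotation screen, operating on loaded gene structures."""
    params = _screen_params(params)
    by_gene: dict[str, list[GeneStructure]] = defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id].append(t)
    for g in by_gene:
        by_gene[g].sort(key=lambda t: t.transcript_id)

    multi = [t for t in transcripts if len(t.exons) > 1]
    n_exons = sum(len(t.exons) for t in multi)

    records = []
    component_edges: dict[tuple[str, str], list[set]] = defaultdict(list)
    for gene_id in sorted(by_gene):
        gene_known = {
            (e.start, e.end) for t in by_gene[gene_id] for e in t.exons
        }
        for t in by_gene[gene_id]:
            if len(t.exons) < 2:
                continue
            result = search_transcript(t, params, known_exon_intervals=gene_known)
            for cluster in result.clusters:
                member_set = {(m.start, m.end) for m in cluster.members}
                component_edges[(gene_id, cluster.classification)].append(member_set)
                for m in cluster.candidates:
                    records.append(
                        {
                            "gene_id": gene_id,
                            "transcript_id": t.transcript_id,
                            "query_exon": cluster.query_exon_index,
                            "classification": cluster.classification,
                            "start": m.start,
                            "end": m.end,
                            "relative_score": round(m.relative_score, 6),
                            "matches_annotated_exon": m.matches_annotated_exon,
                        }
                    )
    records_df = pd.DataFrame(
        records,
        columns=[
            "gene_id", "transcript_id", "query_exon", "classification",
            "start", "end", "relative_score", "matches_annotated_exon",
        ],
    )

    # pool per-transcript clusters per gene: clusters sharing any member
    # interval merge into one gene-level cluster
    predicted: dict[str, dict] = {}
    for cls in ("internal_mxe", "multiple_promoter_like", "multiple_polyA_like", "group_pattern"):
        exons = set()
        genes = set()
        n_clusters = 0
        for (gene_id, c), member_sets in component_edges.items():
            if c != cls:
                continue
            genes.add(gene_id)
            n_clusters += _count_components(member_sets)
            sub = records_df[
                (records_df.gene_id == gene_id) & (records_df.classification == cls)
            ]
            exons.update((gene_id, s, e) for s, e in zip(sub.start, sub.end))
        predicted[cls] = {
            "exons": len(exons),
            "clusters": n_clusters,
            "genes": len(genes),
        }

    ann_clusters = []
    for gene_id in sorted(by_gene):
        ann_clusters.extend(annotated_mxe_clusters(by_gene[gene_id]))
    group_genes = {c.gene_id for c in ann_clusters if c.group_type}
    internal_ann = [
        c for c in ann_clusters
        if c.flanked and not c.group_type and c.gene_id not in group_genes
    ]
    annotated = {
        "internal_clusters": len(internal_ann),
        "internal_exons": sum(len(c.members) for c in internal_ann),
        "terminal_first_clusters": sum(
            1 for c in ann_clusters if c.terminal_side == "first"
        ),
        "terminal_last_clusters": sum(
            1 for c in ann_clusters if c.terminal_side == "last"
        ),
        "group_genes": len(group_genes),
    }

    ann_keys = {
        (c.gene_id, s, e) for c in internal_ann for (s, e) in c.members
    }
    pred_internal = records_df[
        (records_df.classification == "internal_mxe")
        & (~records_df.gene_id.isin(group_genes))
    ]
    pred_keys = {
        (g, s, e)
        for g, s, e in zip(pred_internal.gene_id, pred_internal.start, pred_internal.end)
    }
    all_annotated_exons = {
        (t.gene_id, e.start, e.end) for t in transcripts for e in t.exons
    }
    sensitivity, specificity, match_table = evaluate_against_annotation(
        pred_keys, ann_keys, prediction_overlap_pool=all_annotated_exons
    )
    matched_exact = int((match_table.status == "exact").sum())
    overlap_only = int((match_table.status == "overlap_only").sum())
    new_candidates = len(pred_keys) - matched_exact

    _, neighbour_counts = neighbour_similarity_scan(multi, params)

    return ScreenReport(
        n_genes=len({t.gene_id for t in multi}),
        n_transcripts=len(multi),
        n_exons=n_exons,
        predicted=predicted,
        annotated=annotated,
        matched_exact=matched_exact,
        new_candidates=new_candidates,
        overlap_only=overlap_only,
        neighbour=neighbour_counts,
        sensitivity=sensitivity,
        specificity=specificity,
        records=records_df,
    )


def _count_components(member_sets: list[set]) -> int:
    """Number of connected components among clusters linked by shared members."""
    parent = list(range(len(member_sets)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(member_sets)):
        for j in range(i + 1, len(member_sets)):
            if member_sets[i] & member_sets[j]:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    return len({find(i) for i in range(len(member_sets))})


def chromosome_screen(
    fasta_path, gff3_path, params: SearchParams | None = None
) -> ScreenReport:
    """Run the full screen from a genome FASTA and a GFF3 annotation.

    Transcripts failing structural validation are skipped and listed in the
    report.
    """
    params = _screen_params(params)
    seqs = {s.id: s for s in read_fasta(fasta_path)}
    skipped: list = []
    all_genes = read_gff3(gff3_path, seqs, on_error="skip", skipped=skipped)
    report = screen_structures(all_genes, params)
    report.skipped = skipped
    return report
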