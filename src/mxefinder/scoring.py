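"""Candidate scoring: Gotoh affine-gap global alignment and overlap resolution.

Each candidate translation is aligned globally to the query exon translation
with affine gap costs (a gap run of length L costs gap_open + (L-1) *
gap_extend; defaults -10 / -2) under Blosum62.  Scores are normalized by the
query's self-alignment score, giving a relative score on a scale from zero
(no similarity) to one (identity); candidates below the ``min_score``
threshold are rejected, and overlapping accepted candidates are resolved
greedily by score, then length, then leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .candidates import CandidateInterval
from .errors import ScoringError
from .model import ExonLocus, GeneStructure
from .splice import translate_in_frame

#: Comparison tolerance for the relative-score threshold.
SCORE_EPS = 1e-9


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine gap penalties.

    ``gap_open`` is the total cost of the first position of a gap run and
    ``gap_extend`` the cost of each further position.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = -10
    gap_extend: int = -2

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    arr = mat  # Bio.Align.substitution_matrices.Array, symmetric for BLOSUM62
    return arr


def load_matrix_file(path) -> substitution_matrices.Array:
    """Read a substitution matrix in standard NCBI text format."""
    return substitution_matrices.read(str(path))


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _load_matrix(matrix_name)
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def substitution_score(a: str, b: str, params: AlignmentParams | None = None) -> int:
    params = params or AlignmentParams()
    return int(_load_matrix(params.matrix_name)[a, b])


@dataclass
class ScoredCandidate:
    """A candidate with its translation, scores and reporting alignment."""

    interval: CandidateInterval
    translation: str
    raw_score: int
    self_score: int
    relative_score: float
    accepted: bool
    alignment: tuple[str, str]
    depth: int = 0
    matches_annotated_exon: int | None = None
    is_query: bool = False

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.end - self.interval.start


def _gap_run_cost(length: int, params: AlignmentParams) -> int:
    if length == 0:
        return 0
    return params.gap_open + (length - 1) * params.gap_extend


def gotoh_align(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[int, str, str]:
    """Optimal global affine-gap alignment score and one traceback.

    Terminal gaps are penalized like internal gaps.  Aligning two empty
    sequences scores 0 with an empty alignment.
    """
    params = params or AlignmentParams()
    if not a and not b:
        return 0, "", ""
    if not a or not b:
        n = max(len(a), len(b))
        cost = _gap_run_cost(n, params)
        return cost, a or "-" * n, b or "-" * n
    al = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    alignment = al.align(a, b)[0]
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    return int(round(alignment.score)), gapped_a, gapped_b


def self_score(seq: str, params: AlignmentParams | None = None) -> int:
    """Alignment score of a sequence against itself."""
    raw, _, _ = gotoh_align(seq, seq, params)
    return raw


def relative_score(
    candidate_aa: str, query_aa: str, params: AlignmentParams | None = None
) -> float:
    """Alignment score of candidate vs query divided by the query self-score."""
    params = params or AlignmentParams()
    s_self = self_score(query_aa, params)
    if s_self <= 0:
        raise ScoringError(
            f"query translation {query_aa!r} has non-positive self-score {s_self}"
        )
    raw, _, _ = gotoh_align(candidate_aa, query_aa, params)
    return raw / s_self


def _candidate_translation(
    gene: GeneStructure, query_exon: ExonLocus, interval: CandidateInterval
) -> str:
    """Translate a candidate body in the query's frame with the query's
    split-codon completions (taken from the flanking constitutive exons)."""
    body = gene.sequence.residues[interval.start : interval.end]
    return translate_in_frame(
        body,
        query_exon.start_phase,
        gene.upstream_completion(query_exon.index),
        gene.downstream_completion(query_exon.index),
    )


def score_candidates(
    query_exon: ExonLocus,
    candidates: list[CandidateInterval],
    gene: GeneStructure,
    params: "SearchParams",
) -> list[ScoredCandidate]:
    """Translate, align and threshold candidates against the query exon.

    Candidates whose in-frame translation contains a stop codon are dropped
    before alignment; candidates translating to more than 50% X are dropped
    as degenerate.  The remainder are scored and marked accepted iff their
    relative score reaches ``params.min_score``.
    """
    ap = params.alignment
    query_aa = gene.exon_protein(query_exon.index)
    s_self = self_score(query_aa, ap)
    if s_self <= 0:
        raise ScoringError(
            f"exon {query_exon.index}: non-positive self-score {s_self}"
        )
    out = []
    for cand in candidates:
        aa = _candidate_translation(gene, query_exon, cand)
        if "*" in aa:
            continue
        if aa and aa.count("X") * 2 > len(aa):
            continue
        raw, gapped_a, gapped_b = gotoh_align(aa, query_aa, ap)
        rel = raw / s_self
        out.append(
            ScoredCandidate(
                interval=cand,
                translation=aa,
                raw_score=raw,
                self_score=s_self,
                relative_score=rel,
                accepted=rel >= params.min_score - SCORE_EPS,
                alignment=(gapped_a, gapped_b),
            )
        )
    return out


def _selection_key(c: ScoredCandidate) -> tuple:
    return (-round(c.relative_score, 9), -c.length, c.start, c.end)


def overlaps(a: ScoredCandidate, b: ScoredCandidate) -> bool:
    """Two candidates overlap iff they share at least one genomic base."""
    return a.start < b.end and b.start < a.end


def resolve_overlaps(scored: list[ScoredCandidate]) -> list[ScoredCandidate]:
    """Greedy selection of non-overlapping accepted candidates.

    Ordered by relative score (desc), then DNA length (desc), then leftmost
    start; a candidate is kept iff it overlaps no already-kept candidate.
    The result is independent of the input order.
    """
    kept: list[ScoredCandidate] = []
    for cand in sorted((c for c in scored if c.accepted), key=_selection_key):
        if all(not overlaps(cand, k) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.start)
    return kept
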