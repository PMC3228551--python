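"""Deterministic generator of synthetic genes with planted MXE clusters.

Fixtures emulate the gene architectures the search is designed for: a
multi-exon gene with canonical GT---AG introns, homologous exon copies
implanted into introns at controlled amino-acid divergence, tandem arrays
of whole-gene duplicates, and trans-spliced-like parallel exon groups.
Every fixture ships a ground-truth table with the exact genomic interval
and true identity of each planted copy, so recovery can be measured with
exact borders.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GenerationError
from .model import (
    GeneStructure,
    GenomicSequence,
    STOP_CODONS,
    derive_gene_structure,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_BY_AA: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl

for _codon, _aa in sorted(_tbl.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)

TRUTH_COLUMNS = [
    "kind", "label", "query_exon", "start", "end", "identity", "copy"
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic gene.

    ``implants`` is a list of (exon_index, n_copies, aa_substitution_rate,
    indel_codon_rate) tuples; copies are placed in an intron flanking the
    exon with splice dinucleotides and frame-preserving lengths guaranteed
    by construction.
    """

    seed: int = 0
    n_exons: int = 3
    exon_aa_lengths: tuple[int, ...] | None = None
    intron_lengths: tuple[int, ...] = (120,)
    implants: tuple[tuple[int, int, float, float], ...] = ()
    architecture: str = "simple"
    gc_background: float = 0.5
    flank_length: int = 300

    def __post_init__(self):
        if self.n_exons < 1:
            raise GenerationError("need at least one exon")
        if any(n < 20 for n in self.intron_lengths):
            raise GenerationError("intron lengths must be >= 20 nt")
        if not 0.0 < self.gc_background < 1.0:
            raise GenerationError("gc_background must be in (0, 1)")


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _random_codon(rng: np.random.Generator, aa: str) -> str:
    options = _CODONS_BY_AA[aa]
    return options[rng.integers(len(options))]


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "M" + "".join(
        _AA[rng.integers(len(_AA))] for _ in range(n_aa - 1)
    )


def _mutate_codons(
    codons: list[str],
    mutable: list[bool],
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[list[str], float]:
    """Codon-level substitutions and whole-codon indels, stop codons avoided.

    Returns the mutated codon list and the amino-acid identity fraction
    (substituted codons over mutable codons; indels do not enter identity).
    """
    out: list[str] = []
    n_sub = 0
    n_mut = max(1, sum(mutable))
    for codon, can in zip(codons, mutable):
        if can and sub_rate > 0 and rng.random() < sub_rate:
            aa = _tbl.forward_table[codon]
            choices = [x for x in _AA if x != aa]
            codon = _random_codon(rng, choices[rng.integers(len(choices))])
            n_sub += 1
        if can and indel_rate > 0 and rng.random() < indel_rate / 2:
            pass  # whole-codon deletion
        else:
            out.append(codon)
        if can and indel_rate > 0 and rng.random() < indel_rate / 2:
            out.append(_random_codon(rng, _AA[rng.integers(len(_AA))]))
    if not out:
        out = [codons[0]]
    return out, 1.0 - n_sub / n_mut


def _mutable_mask(
    n_codons: int, up_len: int, down_len: int, keep_first: bool
) -> list[bool]:
    mask = [True] * n_codons
    if up_len:
        mask[0] = False
    if down_len:
        mask[-1] = False
    if keep_first:
        mask[0] = False
    return mask


def random_gene(spec: FixtureSpec) -> tuple[GenomicSequence, GeneStructure, pd.DataFrame]:
    """Generate a validated gene with canonical splice sites and implants.

    The CDS starts with ATG, is free of in-frame stops by construction and
    is followed by a stop codon.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    aa_lengths = spec.exon_aa_lengths or tuple([30] * spec.n_exons)
    if len(aa_lengths) != spec.n_exons:
        raise GenerationError("exon_aa_lengths length must equal n_exons")
    protein = _random_protein(rng, sum(aa_lengths))
    codons = [_random_codon(rng, aa) for aa in protein]

    pieces: list[str] = []
    coords: list[tuple[int, int]] = []
    pos = spec.flank_length
    pieces.append(_random_background(rng, spec.flank_length, spec.gc_background))
    ci = 0
    for i, n_aa in enumerate(aa_lengths):
        exon_dna = "".join(codons[ci : ci + n_aa])
        ci += n_aa
        coords.append((pos, pos + len(exon_dna)))
        pieces.append(exon_dna)
        pos += len(exon_dna)
        if i < spec.n_exons - 1:
            n = spec.intron_lengths[i % len(spec.intron_lengths)]
            intron = "GT" + _random_background(rng, n - 4, spec.gc_background) + "AG"
            pieces.append(intron)
            pos += n
    pieces.append("TAA")
    pieces.append(_random_background(rng, spec.flank_length, spec.gc_background))
    seq = GenomicSequence(id=f"synth{spec.seed}", residues="".join(pieces))
    gene = derive_gene_structure(coords, seq, transcript_id=f"t{spec.seed}",
                                 gene_id=f"g{spec.seed}")

    rows: list[dict] = []
    for exon_index, n_copies, sub_rate, indel_rate in spec.implants:
        for copy in range(n_copies):
            gene, rec = implant_homolog(
                gene,
                exon_index,
                aa_substitution_rate=sub_rate,
                indel_codon_rate=indel_rate,
                rng=rng,
                forbidden=[(r["start"], r["end"]) for r in rows],
            )
            # earlier truth intervals shift if the insert landed before them
            for r in rows:
                if r["start"] >= rec["insert_pos"]:
                    r["start"] += rec["insert_len"]
                    r["end"] += rec["insert_len"]
            rows.append(
                {
                    "kind": "implant",
                    "label": f"exon{exon_index}_copy{copy}",
                    "query_exon": exon_index,
                    "start": rec["start"],
                    "end": rec["end"],
                    "identity": rec["identity"],
                    "copy": copy,
                }
            )
    return gene.sequence, gene, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def implant_homolog(
    gene: GeneStructure,
    exon_index: int,
    aa_substitution_rate: float = 0.0,
    indel_codon_rate: float = 0.0,
    intron_index: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_new_intron_length: int = 4,
    forbidden: list[tuple[int, int]] | None = None,
) -> tuple[GeneStructure, dict]:
    """Insert a diverged copy of an exon into an intron of the gene.

    The copy receives splice dinucleotides compatible with the flanking
    intron context of the query exon (AG before / GT after for internal
    exons; an ATG start for the first exon; a TAA after the copy of a last
    exon).  Substitutions and whole-codon indels are applied at the stated
    rates, avoiding stop codons and leaving split-codon edges untouched.
    Returns the rebuilt gene and a ground-truth record with the copy's
    exact interval.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    exon = gene.exons[exon_index]
    if intron_index is None:
        intron_index = min(exon_index, len(gene.introns) - 1)
    if not gene.introns:
        raise GenerationError("cannot implant into a gene without introns")
    intron = gene.introns[intron_index]

    up = gene.upstream_completion(exon_index)
    down = gene.downstream_completion(exon_index)
    completed = up + gene.exon_dna(exon_index) + down
    codons = [completed[i : i + 3] for i in range(0, len(completed), 3)]
    mutable = _mutable_mask(len(codons), len(up), len(down), exon.is_first)
    mutated, identity = _mutate_codons(
        codons, mutable, aa_substitution_rate, indel_codon_rate, rng
    )
    joined = "".join(mutated)
    body = joined[len(up) : len(joined) - len(down) if down else None]
    if len(body) < 3:
        raise GenerationError("mutated implant body shorter than one codon")

    if exon.is_first and exon.is_last:
        unit, offset = body + "TAA", 0
    elif exon.is_first:
        unit, offset = body + "GT", 0
    elif exon.is_last:
        unit, offset = "AG" + body + "TAA", 2
    else:
        unit, offset = "AG" + body + "GT", 2

    margin = max(min_new_intron_length, 4)
    if intron.length < len(body) + 2 * (margin + 2):
        raise GenerationError(
            f"intron {intron_index} ({intron.length} nt) too short for a "
            f"{len(body)}-nt implant with {margin}-nt margins"
        )
    lo, hi = intron.start + margin, intron.end - margin
    forbidden = forbidden or []
    pos = None
    for _ in range(200):
        p = int(rng.integers(lo, hi))
        if all(not (s - 2 < p < e + 2) for s, e in forbidden):
            pos = p
            break
    if pos is None:
        raise GenerationError("no implant position available outside prior implants")

    res = gene.sequence.residues
    new_res = res[:pos] + unit + res[pos:]
    new_coords = [
        (s + len(unit), e + len(unit)) if s >= pos else (s, e)
        for s, e in ((x.start, x.end) for x in gene.exons)
    ]
    new_seq = GenomicSequence(id=gene.sequence.id, residues=new_res)
    new_gene = derive_gene_structure(
        new_coords,
        new_seq,
        transcript_id=gene.transcript_id,
        gene_id=gene.gene_id,
        strand=gene.strand,
    )
    start = pos + offset
    record = {
        "query_exon": exon_index,
        "start": start,
        "end": start + len(body),
        "identity": identity,
        "insert_pos": pos,
        "insert_len": len(unit),
    }
    return new_gene, record


def _mutate_exon_body(
    gene: GeneStructure, exon_index: int, rate: float, rng: np.random.Generator
) -> str:
    exon = gene.exons[exon_index]
    up = gene.upstream_completion(exon_index)
    down = gene.downstream_completion(exon_index)
    completed = up + gene.exon_dna(exon_index) + down
    codons = [completed[i : i + 3] for i in range(0, len(completed), 3)]
    mutable = _mutable_mask(len(codons), len(up), len(down), exon.is_first)
    mutated, _ = _mutate_codons(codons, mutable, rate, 0.0, rng)
    joined = "".join(mutated)
    return joined[len(up) : len(joined) - len(down) if down else None]


def make_tandem_array(
    gene: GeneStructure,
    n_copies: int,
    divergence: float = 0.0,
    spacer_length: int = 200,
    seed: int = 0,
    flank_length: int = 300,
    gc_background: float = 0.5,
) -> tuple[GenomicSequence, GeneStructure, pd.DataFrame]:
    """Arrange n whole-gene copies in tandem; only the first is annotated.

    Every copy keeps the original intron sequences; exon bodies diverge at
    the given amino-acid substitution rate.  The ground truth labels every
    exon of every copy, enabling group-pattern tests.
    """
    if n_copies < 1:
        raise GenerationError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    first, last = gene.exons[0], gene.exons[-1]
    res = gene.sequence.residues
    intron_seqs = [res[i.start : i.end] for i in gene.introns]

    pieces = [_random_background(rng, flank_length, gc_background)]
    pos = flank_length
    coords_first: list[tuple[int, int]] = []
    truth_rows = []
    for copy in range(n_copies):
        for j, exon in enumerate(gene.exons):
            body = (
                gene.exon_dna(j)
                if copy == 0
                else _mutate_exon_body(gene, j, divergence, rng)
            )
            if copy == 0:
                coords_first.append((pos, pos + len(body)))
            truth_rows.append(
                {
                    "kind": "tandem_exon",
                    "label": f"copy{copy}_exon{j}",
                    "query_exon": j,
                    "start": pos,
                    "end": pos + len(body),
                    "identity": 1.0 if copy == 0 else 1.0 - divergence,
                    "copy": copy,
                }
            )
            pieces.append(body)
            pos += len(body)
            if j < len(gene.exons) - 1:
                pieces.append(intron_seqs[j])
                pos += len(intron_seqs[j])
        pieces.append("TAA")
        pos += 3
        if copy < n_copies - 1:
            pieces.append(_random_background(rng, spacer_length, gc_background))
            pos += spacer_length
    pieces.append(_random_background(rng, flank_length, gc_background))
    seq = GenomicSequence(id=f"tandem{seed}", residues="".join(pieces))
    annotated = derive_gene_structure(
        coords_first, seq, transcript_id=f"t_tandem{seed}", gene_id=f"g_tandem{seed}"
    )
    return seq, annotated, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def make_screen_fixture(
    seed: int = 0,
    n_plain: int = 6,
    n_mxe: int = 3,
    n_terminal: int = 1,
    divergence: float = 0.1,
) -> tuple[list[GenomicSequence], list[GeneStructure], pd.DataFrame]:
    """A small multi-gene annotation with known ground truth for the screen.

    ``n_mxe`` genes carry an annotated internal MXE pair (two transcripts,
    each using one alternative of the middle exon); ``n_terminal`` genes
    carry an alternative first exon (a multiple-promoter-like pair); the
    rest are plain multi-exon genes.  Each gene sits on its own sequence.
    """
    seqs: list[GenomicSequence] = []
    transcripts: list[GeneStructure] = []
    rows = []
    gi = 0

    def add_alternative(kind: str, exon_index: int, sub_seed: int):
        nonlocal gi
        spec = FixtureSpec(
            seed=sub_seed,
            n_exons=4,
            exon_aa_lengths=(22, 30, 26, 24),
            intron_lengths=(150, 170, 140),
            implants=((exon_index, 1, divergence, 0.0),),
        )
        seq, gene, truth = random_gene(spec)
        gene_id = f"g{gi:03d}"
        t1 = derive_gene_structure(
            [(e.start, e.end) for e in gene.exons], seq,
            transcript_id=f"{gene_id}.t1", gene_id=gene_id,
        )
        alt = (int(truth.iloc[0]["start"]), int(truth.iloc[0]["end"]))
        coords2 = [
            alt if e.index == exon_index else (e.start, e.end)
            for e in gene.exons
        ]
        t2 = derive_gene_structure(
            sorted(coords2), seq, transcript_id=f"{gene_id}.t2", gene_id=gene_id
        )
        seqs.append(seq)
        transcripts.extend([t1, t2])
        orig = gene.exons[exon_index]
        rows.append(
            {
                "gene_id": gene_id, "kind": kind, "exon_index": exon_index,
                "member_a": (orig.start, orig.end), "member_b": alt,
            }
        )
        gi += 1

    for k in range(n_mxe):
        add_alternative("internal_mxe", 1, seed * 1009 + k)
    for k in range(n_terminal):
        add_alternative("terminal_first", 0, seed * 1009 + 500 + k)
    for k in range(n_plain):
        spec = FixtureSpec(
            seed=seed * 1009 + 800 + k,
            n_exons=3,
            exon_aa_lengths=(20, 28, 22),
            intron_lengths=(130, 160),
        )
        seq, gene, _ = random_gene(spec)
        gene_id = f"g{gi:03d}"
        t1 = derive_gene_structure(
            [(e.start, e.end) for e in gene.exons], seq,
            transcript_id=f"{gene_id}.t1", gene_id=gene_id,
        )
        seqs.append(seq)
        transcripts.append(t1)
        rows.append(
            {
                "gene_id": gene_id, "kind": "plain", "exon_index": -1,
                "member_a": None, "member_b": None,
            }
        )
        gi += 1
    truth = pd.DataFrame(
        rows, columns=["gene_id", "kind", "exon_index", "member_a", "member_b"]
    )
    return seqs, transcripts, truth


def make_trans_spliced_fixture(
    seed: int = 0,
    group_aa_lengths: tuple[int, ...] = (25, 30, 28),
    divergence: float = 0.05,
    gc_background: float = 0.5,
) -> tuple[GenomicSequence, GeneStructure, pd.DataFrame]:
    """A trans-spliced-like gene: shared first exon + two parallel 3' groups.

    The annotated transcript (isoform A) consists of the common first exon
    and group-A exons; homologous group-B exons sit, with their own
    compatible splice contexts, inside the first intron of isoform A.  A
    surrounding-introns search therefore proposes the first group-B exon as
    a misleading MXE candidate, while an all-introns search reveals the
    parallel group that the group-pattern detector flags.
    """
    rng = np.random.default_rng(seed)
    base = FixtureSpec(
        seed=seed,
        n_exons=1 + len(group_aa_lengths),
        exon_aa_lengths=(20,) + tuple(group_aa_lengths),
        intron_lengths=(80,),
        gc_background=gc_background,
    )
    _, gene_a, _ = random_gene(base)

    b_bodies = [
        _mutate_exon_body(gene_a, 1 + j, divergence, rng)
        for j in range(len(group_aa_lengths))
    ]
    filler = 30
    interior = [_random_background(rng, filler, gc_background)]
    b_local = []
    off = filler
    for j, body in enumerate(b_bodies):
        stop_side = j == len(b_bodies) - 1
        interior.append("AG")
        off += 2
        b_local.append((off, off + len(body)))
        interior.append(body)
        off += len(body)
        interior.append("TAA" if stop_side else "GT")
        off += 3 if stop_side else 2
        interior.append(_random_background(rng, filler, gc_background))
        off += filler
    insert = "".join(interior)

    intron0 = gene_a.introns[0]
    pos = intron0.start + 10
    res = gene_a.sequence.residues
    new_res = res[:pos] + insert + res[pos:]
    new_coords = [
        (s + len(insert), e + len(insert)) if s >= pos else (s, e)
        for s, e in ((x.start, x.end) for x in gene_a.exons)
    ]
    seq = GenomicSequence(id=f"trans{seed}", residues=new_res)
    annotated = derive_gene_structure(
        new_coords, seq, transcript_id=f"t_trans{seed}", gene_id=f"g_trans{seed}"
    )
    rows = []
    for j, exon_idx in enumerate(range(1, 1 + len(group_aa_lengths))):
        e = annotated.exons[exon_idx]
        rows.append(
            {
                "kind": "group_exon", "label": f"A{j}", "query_exon": exon_idx,
                "start": e.start, "end": e.end, "identity": 1.0, "copy": 0,
            }
        )
    for j, (s, e) in enumerate(b_local):
        rows.append(
            {
                "kind": "group_exon", "label": f"B{j}", "query_exon": 1 + j,
                "start": pos + s, "end": pos + e,
                "identity": 1.0 - divergence, "copy": 1,
            }
        )
    return seq, annotated, pd.DataFrame(rows, columns=TRUTH_COLUMNS)
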