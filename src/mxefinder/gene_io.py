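"""Reading sequences and gene structures; writing search results.

FASTA is read with Biopython, GFF3 with gffutils (in-memory db).  Internally
all coordinates are 0-based half-open on the forward-normalized gene axis;
GFF3 I/O converts to/from 1-based inclusive coordinates and maps
minus-strand results back to the original strand.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO

from .errors import FormatError, StructureError
from .model import (
    GeneStructure,
    GenomicSequence,
    NUCLEOTIDES,
    derive_gene_structure,
    reverse_complement,
)


def read_fasta(path) -> list[GenomicSequence]:
    """Read a (multi-)FASTA file into GenomicSequence records.

    Residues are uppercased and U is mapped to T; characters outside
    {A,C,G,T,N} raise a FormatError naming the record and position.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("U", "T")
        bad = set(residues) - NUCLEOTIDES
        if bad:
            pos = next(i for i, c in enumerate(residues) if c in bad)
            raise FormatError(
                f"{path}: record {rec.id!r}: illegal character "
                f"{residues[pos]!r} at position {pos + 1}"
            )
        records.append(GenomicSequence(id=rec.id, residues=residues))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _transcript_features(db):
    ids = set()
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            if feat.id not in ids:
                ids.add(feat.id)
                yield feat


def read_gff3(
    path,
    seqs: dict[str, GenomicSequence] | list[GenomicSequence],
    on_error: str = "raise",
    skipped: list | None = None,
) -> list[GeneStructure]:
    """Read gene structures (one per mRNA) from a GFF3 annotation.

    CDS features define the exons; minus-strand transcripts are
    reverse-complement-normalized so that all downstream logic is
    strand-free.  Phases are recomputed from scratch and checked against
    the file's phases where present.  With ``on_error="skip"`` transcripts
    failing validation are silently omitted instead of raising.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    if isinstance(seqs, list):
        seqs = {s.id: s for s in seqs}
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    rc_cache: dict[str, GenomicSequence] = {}
    out = []
    for mrna in _transcript_features(db):
        try:
            out.append(_build_structure(db, mrna, seqs, rc_cache))
        except (FormatError, StructureError) as exc:
            if on_error == "raise":
                raise
            if skipped is not None:
                skipped.append((mrna.id, str(exc)))
    return out


def _build_structure(db, mrna, seqs, rc_cache) -> GeneStructure:
    if mrna.seqid not in seqs:
        raise FormatError(
            f"transcript {mrna.id!r}: seqid {mrna.seqid!r} absent from FASTA"
        )
    seq = seqs[mrna.seqid]
    cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
    if not cds:
        cds = list(db.children(mrna, featuretype="exon", order_by="start"))
    if not cds:
        raise StructureError(f"transcript {mrna.id!r}: no CDS/exon children")
    strand = mrna.strand if mrna.strand in ("+", "-") else "+"
    coords = [(f.start - 1, f.end) for f in cds]  # to 0-based half-open
    file_phases = [f.frame if f.frame in ("0", "1", "2") else None for f in cds]
    for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
        if s2 < e1:
            raise StructureError(
                f"transcript {mrna.id!r}: overlapping CDS ({s1},{e1})/({s2},{e2})"
            )
    if strand == "-":
        if seq.id not in rc_cache:
            rc_cache[seq.id] = GenomicSequence(
                id=seq.id, residues=reverse_complement(seq.residues)
            )
        norm_seq = rc_cache[seq.id]
        L = seq.length
        coords = sorted((L - e, L - s) for s, e in coords)
        file_phases = file_phases[::-1]
    else:
        norm_seq = seq
    parents = list(db.parents(mrna, featuretype="gene"))
    gene_id = parents[0].id if parents else mrna.attributes.get("Parent", [mrna.id])[0]
    gene = derive_gene_structure(
        coords,
        norm_seq,
        transcript_id=mrna.id,
        gene_id=gene_id,
        strand=strand,
    )
    for exon, fph in zip(gene.exons, file_phases):
        if fph is not None and int(fph) != exon.start_phase:
            raise StructureError(
                f"transcript {mrna.id!r}: CDS phase {fph} in file, "
                f"{exon.start_phase} recomputed for exon {exon.index}"
            )
    return gene


def _attr(pairs) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def _to_file_coords(gene: GeneStructure, start: int, end: int) -> tuple[int, int]:
    """Normalized half-open -> original-strand 1-based inclusive."""
    if gene.strand == "-":
        L = gene.sequence.length
        return L - end + 1, L - start
    return start + 1, end


def write_gff3(result, path) -> None:
    """Write the original exons plus one feature per accepted candidate.

    Candidate features carry cluster_id, relative_score (4 decimals),
    recursion_depth and classification attributes and re-parse into the
    same candidate set.
    """
    gene = result.gene
    lines = ["##gff-version 3"]
    seqid = gene.sequence.id
    tid = gene.transcript_id
    if gene.exons:
        g_start, g_end = gene.exons[0].start, gene.exons[-1].end
        s, e = _to_file_coords(gene, g_start, g_end)
        lines.append(
            "\t".join(
                [
                    seqid, "mxefinder", "mRNA", str(min(s, e)), str(max(s, e)),
                    ".", gene.strand, ".", _attr([("ID", tid), ("Parent", gene.gene_id)]),
                ]
            )
        )
    for exon in gene.exons:
        s, e = _to_file_coords(gene, exon.start, exon.end)
        lines.append(
            "\t".join(
                [
                    seqid, "mxefinder", "CDS", str(s), str(e), ".",
                    gene.strand, str(exon.start_phase),
                    _attr([("ID", f"{tid}.cds{exon.index}"), ("Parent", tid)]),
                ]
            )
        )
    for cluster in result.clusters:
        cid = f"{tid}.cluster{cluster.query_exon_index}"
        for k, member in enumerate(cluster.members):
            s, e = _to_file_coords(gene, member.start, member.end)
            name = f"{cid}.query" if member.is_query else f"{cid}.alt{k}"
            lines.append(
                "\t".join(
                    [
                        seqid, "mxefinder", "exon", str(s), str(e),
                        f"{member.relative_score:.4f}", gene.strand,
                        str(gene.exons[cluster.query_exon_index].start_phase),
                        _attr(
                            [
                                ("ID", name),
                                ("Parent", tid),
                                ("cluster_id", cid),
                                ("is_query", "1" if member.is_query else "0"),
                                ("relative_score", f"{member.relative_score:.4f}"),
                                ("recursion_depth", str(member.depth)),
                                ("classification", cluster.classification),
                            ]
                        ),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gff3_candidates(path) -> list[dict]:
    """Parse candidate features back from a written GFF3 (round-trip aid)."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if cols[2] != "exon":
            continue
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
        out.append(
            {
                "seqid": cols[0],
                "start": int(cols[3]),
                "end": int(cols[4]),
                "strand": cols[6],
                "cluster_id": attrs["cluster_id"],
                "is_query": attrs["is_query"] == "1",
                "relative_score": float(attrs["relative_score"]),
                "recursion_depth": int(attrs["recursion_depth"]),
                "classification": attrs["classification"],
            }
        )
    return out


def _result_document(result) -> dict:
    gene = result.gene
    return {
        "format": "mxefinder-result/1",
        "gene": {
            "transcript_id": gene.transcript_id,
            "gene_id": gene.gene_id,
            "sequence_id": gene.sequence.id,
            "strand": gene.strand,
            "exons": [[e.start, e.end] for e in gene.exons],
        },
        "params": dataclasses.asdict(result.params),
        "clusters": [
            {
                "query_exon": c.query_exon_index,
                "classification": c.classification,
                "recursion_rounds_used": c.recursion_rounds_used,
                "members": [
                    {
                        "start": m.start,
                        "end": m.end,
                        "is_query": m.is_query,
                        "translation": m.translation,
                        "raw_score": m.raw_score,
                        "self_score": m.self_score,
                        "relative_score": m.relative_score,
                        "recursion_depth": m.depth,
                        "region_role": (
                            m.interval.source_region.role
                            if m.interval.source_region
                            else None
                        ),
                        "matches_annotated_exon": m.matches_annotated_exon,
                        "alignment": list(m.alignment),
                    }
                    for m in c.members
                ],
            }
            for c in result.clusters
        ],
        "log": result.log,
    }


def write_result_yaml(result, path) -> None:
    """Serialize a search result to the package's YAML schema (lossless)."""
    doc = _result_document(result)
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )


def read_result_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))


def result_table(result) -> pd.DataFrame:
    """One row per cluster member (query exon flagged by is_query)."""
    rows = []
    gene = result.gene
    for c in result.clusters:
        for m in c.members:
            rows.append(
                {
                    "transcript_id": gene.transcript_id,
                    "gene_id": gene.gene_id,
                    "query_exon": c.query_exon_index,
                    "classification": c.classification,
                    "start": m.start,
                    "end": m.end,
                    "length_nt": m.length,
                    "is_query": m.is_query,
                    "relative_score": round(m.relative_score, 6),
                    "recursion_depth": m.depth,
                    "translation": m.translation,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "query_exon", "classification",
            "start", "end", "length_nt", "is_query", "relative_score",
            "recursion_depth", "translation",
        ],
    )


def write_tsv(result, path) -> None:
    result_table(result).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_fasta(seqs: list[GenomicSequence], path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, s.length, width):
                fh.write(s.residues[i : i + width] + "\n")


def write_annotation_gff3(transcripts: list, path) -> None:
    """Write gene/mRNA/CDS features for forward-strand gene structures."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id in sorted(by_gene):
        ts = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
        seqid = ts[0].sequence.id
        g_start = min(t.exons[0].start for t in ts) + 1
        g_end = max(t.exons[-1].end for t in ts)
        lines.append(
            "\t".join(
                [seqid, "synthfix", "gene", str(g_start), str(g_end), ".",
                 "+", ".", f"ID={gene_id}"]
            )
        )
        for t in ts:
            lines.append(
                "\t".join(
                    [seqid, "synthfix", "mRNA",
                     str(t.exons[0].start + 1), str(t.exons[-1].end), ".",
                     "+", ".", f"ID={t.transcript_id};Parent={gene_id}"]
                )
            )
            for e in t.exons:
                lines.append(
                    "\t".join(
                        [seqid, "synthfix", "CDS", str(e.start + 1), str(e.end),
                         ".", "+", str(e.start_phase),
                         f"ID={t.transcript_id}.cds{e.index};Parent={t.transcript_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
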