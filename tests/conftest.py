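import numpy as np
import pytest

from mxefinder.model import GenomicSequence, derive_gene_structure


def build_gene(exon_bodies, intron_seqs, flank_up="CCCCCCCCCCCC",
               flank_down="CCCCCCCCCCCC", stop="TAA", transcript_id="t1",
               gene_id="g1", seq_id="chr"):
    """Assemble a gene from explicit exon and intron strings.

    Introns must include their own boundary dinucleotides.  A stop codon is
    placed immediately after the last exon.  Returns (sequence, gene).
    """
    assert len(intron_seqs) == len(exon_bodies) - 1
    pieces = [flank_up]
    pos = len(flank_up)
    coords = []
    for i, body in enumerate(exon_bodies):
        coords.append((pos, pos + len(body)))
        pieces.append(body)
        pos += len(body)
        if i < len(intron_seqs):
            pieces.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    pieces.append(stop)
    pieces.append(flank_down)
    seq = GenomicSequence(id=seq_id, residues="".join(pieces))
    gene = derive_gene_structure(coords, seq, transcript_id=transcript_id,
                                 gene_id=gene_id)
    return seq, gene


@pytest.fixture
def simple_gene():
    """Three phase-0 exons with canonical GT..AG introns."""
    return build_gene(
        ["ATGGCTGAAAAAGGT", "TGGCACGATCCTTTC", "GGTCGCATTGCCTAG".replace("TAG", "TCC")],
        ["GT" + "ATATATATATATATAT" + "AG", "GT" + "CGCGCGCGCGCGCGCG" + "AG"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
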