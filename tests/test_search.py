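"""Per-exon search, clusters, recursion, classification and group patterns."""

import numpy as np
import pytest

from mxefinder.gene_io import _result_document
from mxefinder.model import GenomicSequence, derive_gene_structure, reverse_complement
from mxefinder.scoring import relative_score
from mxefinder.splice import translate_in_frame
from mxefinder.search import (
    SearchParams,
    classify_cluster,
    recursive_expand,
    search_exon,
    search_transcript,
)
from mxefinder.synthfix import (
    FixtureSpec,
    implant_homolog,
    make_tandem_array,
    make_trans_spliced_fixture,
    random_gene,
)


def members_of(result, qi):
    for c in result.clusters:
        if c.query_exon_index == qi:
            return {(m.start, m.end) for m in c.members}
    return None


class TestSearchExon:
    def test_exact_copy_recovered_with_exact_borders(self):
        spec = FixtureSpec(seed=7, n_exons=3, exon_aa_lengths=(20, 30, 22),
                           intron_lengths=(150, 200),
                           implants=((1, 1, 0.0, 0.0),))
        _, gene, truth = random_gene(spec)
        cluster = search_exon(gene, 1, SearchParams())
        assert len(cluster.members) == 2
        cand = cluster.candidates[0]
        assert (cand.start, cand.end) == (
            int(truth.iloc[0]["start"]), int(truth.iloc[0]["end"])
        )
        assert cand.relative_score == pytest.approx(1.0)

    def test_incompatible_introns_give_trivial_cluster(self):
        # a gene without compatible dinucleotide hits in its introns
        spec = FixtureSpec(seed=8, n_exons=3, exon_aa_lengths=(20, 30, 22),
                           intron_lengths=(100, 100))
        _, gene, _ = random_gene(spec)
        # spurious hits are possible but must then satisfy every filter
        cluster = search_exon(gene, 1, SearchParams())
        exon = gene.exons[1]
        for cand in cluster.candidates:
            assert (cand.length - exon.length) % 3 == 0
            assert cand.relative_score >= 0.15 - 1e-9
            assert "*" not in cand.translation

    def test_short_query_skipped_with_log(self):
        spec = FixtureSpec(seed=9, n_exons=3, exon_aa_lengths=(20, 10, 22),
                           intron_lengths=(100, 100))
        _, gene, _ = random_gene(spec)
        log = []
        cluster = search_exon(gene, 1, SearchParams(), log)
        assert cluster.is_trivial
        assert any("shorter" in e["reason"] for e in log)


class TestSearchTranscript:
    def test_one_nontrivial_cluster_for_one_implant(self):
        spec = FixtureSpec(seed=10, n_exons=3, exon_aa_lengths=(20, 30, 22),
                           intron_lengths=(150, 200),
                           implants=((1, 1, 0.0, 0.0),))
        _, gene, _ = random_gene(spec)
        result = search_transcript(gene, SearchParams())
        assert [c.query_exon_index for c in result.clusters] == [1]

    def test_single_exon_terminal_searches_off(self):
        body = "ATG" + "GCTGAAGCTCATGCTTCATTAGCTCAT" * 2
        seq = GenomicSequence("s", "C" * 20 + body + "TAA" + "C" * 20)
        gene = derive_gene_structure([(20, 20 + len(body))], seq)
        params = SearchParams(search_with_start_codon="off",
                              search_with_stop_codon="off",
                              search_updownstream=True)
        result = search_transcript(gene, params)
        assert result.clusters == []
        assert any("disabled" in e["reason"] for e in result.log)

    def test_non_met_protein_disables_first_exon_search(self):
        # auto mode: first exon is not searched when the protein does not
        # start with methionine
        spec = FixtureSpec(seed=12, n_exons=3, exon_aa_lengths=(20, 30, 22),
                          intron_lengths=(150, 150), implants=((0, 1, 0.0, 0.0),))
        _, gene, _ = random_gene(spec)
        # mutate the start codon away (ATG -> CTG) to make a non-M protein
        res = gene.sequence.residues
        e0 = gene.exons[0]
        res2 = res[: e0.start] + "CTG" + res[e0.start + 3 :]
        gene2 = derive_gene_structure(
            [(e.start, e.end) for e in gene.exons],
            GenomicSequence("s", res2),
        )
        assert not gene2.starts_with_met
        log = []
        cluster = search_exon(gene2, 0, SearchParams(), log)
        assert cluster.is_trivial
        assert any("disabled" in e["reason"] for e in log)
        # explicit override re-enables the ATG-anchored search
        cluster_on = search_exon(gene2, 0, SearchParams(search_with_start_codon="on"))
        assert len(cluster_on.members) == 2

    def test_determinism(self):
        spec = FixtureSpec(seed=13, n_exons=4, exon_aa_lengths=(22, 30, 26, 24),
                           intron_lengths=(200, 220, 180),
                           implants=((1, 2, 0.1, 0.0), (2, 1, 0.05, 0.0)))
        _, gene, _ = random_gene(spec)
        r1 = search_transcript(gene, SearchParams())
        r2 = search_transcript(gene, SearchParams())
        assert _result_document(r1) == _result_document(r2)

    def test_strand_invariance(self, tmp_path):
        # the same gene presented on the minus strand of the reverse
        # complement must yield coordinate-mirrored, score-identical clusters
        from mxefinder.gene_io import read_fasta, read_gff3

        spec = FixtureSpec(seed=14, n_exons=3, exon_aa_lengths=(20, 30, 22),
                           intron_lengths=(150, 200),
                           implants=((1, 1, 0.1, 0.0),))
        _, gene, _ = random_gene(spec)
        L = gene.sequence.length
        rc = reverse_complement(gene.sequence.residues)
        (tmp_path / "rc.fa").write_text(f">chr\n{rc}\n")
        lines = ["##gff-version 3", f"chr\t.\tmRNA\t1\t{L}\t.\t-\t.\tID=m1"]
        for e in gene.exons:
            lines.append(
                f"chr\t.\tCDS\t{L - e.end + 1}\t{L - e.start}\t.\t-\t"
                f"{e.start_phase}\tID=c{e.index};Parent=m1"
            )
        (tmp_path / "rc.gff3").write_text("\n".join(lines) + "\n")
        (minus,) = read_gff3(
            tmp_path / "rc.gff3", read_fasta(tmp_path / "rc.fa")
        )
        assert minus.strand == "-"
        r_fwd = search_transcript(gene, SearchParams())
        r_rev = search_transcript(minus, SearchParams())
        key = lambda r: {
            (c.query_exon_index,
             frozenset((m.start, m.end, round(m.relative_score, 9))
                       for m in c.members))
            for c in r.clusters
        }
        assert key(r_fwd) == key(r_rev)
        assert key(r_fwd)  # non-empty: the implant was found on both strands


class TestClassification:
    @pytest.mark.parametrize(
        "implant_exon,expected",
        [(0, "multiple_promoter_like"), (1, "internal_mxe"), (3, "multiple_polyA_like")],
    )
    def test_position_based_labels(self, implant_exon, expected):
        spec = FixtureSpec(seed=15, n_exons=4, exon_aa_lengths=(22, 30, 26, 24),
                           intron_lengths=(200, 200, 200),
                           implants=((implant_exon, 1, 0.0, 0.0),))
        _, gene, _ = random_gene(spec)
        result = search_transcript(gene, SearchParams())
        (cluster,) = [c for c in result.clusters if c.query_exon_index == implant_exon]
        assert cluster.classification == expected
        assert classify_cluster(cluster, gene) == expected


def _build_recursion_gene():
    """A cluster where C is reachable only through B.

    B diverges strongly from the query exon E (relative score just above
    threshold); C is a near-identical twin of B whose score against E falls
    below threshold, so C appears only in a recursive round.
    """
    for seed in range(100):
        rng = np.random.default_rng(10_000 + seed)
        spec = FixtureSpec(seed=20_000 + seed, n_exons=3,
                           exon_aa_lengths=(20, 30, 22),
                           intron_lengths=(150, 600))
        _, gene, _ = random_gene(spec)
        gene1, rec_b = implant_homolog(
            gene, 1, aa_substitution_rate=0.55, rng=rng, intron_index=1
        )
        res = gene1.sequence.residues
        b_body = res[rec_b["start"] : rec_b["end"]]

        def _aa(body):
            return translate_in_frame(
                body, gene1.exons[1].start_phase,
                gene1.upstream_completion(1), gene1.downstream_completion(1),
            )

        e_aa1 = gene1.exon_protein(1)
        if not 0.16 <= relative_score(_aa(b_body), e_aa1) <= 0.30:
            continue
        # twin of B: substitute a few codons until its score against the
        # original query drops below threshold
        codons = [b_body[i : i + 3] for i in range(0, len(b_body), 3)]
        for k in range(2, min(len(codons), 20), 2):
            codons[k] = "CCG" if codons[k] != "CCG" else "TGG"
            if relative_score(_aa("".join(codons)), e_aa1) < 0.13:
                break
        c_body = "".join(codons)
        pos = rec_b["end"] + 20
        unit = "AG" + c_body + "GT"
        intr = gene1.introns[1]
        if pos + len(unit) > intr.end - 10:
            continue
        res2 = res[:pos] + unit + res[pos:]
        coords = [
            (e.start + len(unit), e.end + len(unit)) if e.start >= pos else (e.start, e.end)
            for e in gene1.exons
        ]
        gene2 = derive_gene_structure(coords, GenomicSequence("rec", res2))
        c_start = pos + 2
        e_aa = gene2.exon_protein(1)
        b_aa = translate_in_frame(b_body, gene2.exons[1].start_phase,
                                  gene2.upstream_completion(1),
                                  gene2.downstream_completion(1))
        c_aa = translate_in_frame(c_body, gene2.exons[1].start_phase,
                                  gene2.upstream_completion(1),
                                  gene2.downstream_completion(1))
        rel_be = relative_score(b_aa, e_aa)
        rel_ce = relative_score(c_aa, e_aa)
        rel_cb = relative_score(c_aa, b_aa)
        if 0.17 <= rel_be <= 0.45 and rel_ce < 0.13 and rel_cb >= 0.5:
            return gene2, (rec_b["start"], rec_b["end"]), (c_start, c_start + len(c_body))
    raise AssertionError("no suitable recursion fixture found")


@pytest.fixture(scope="module")
def recursion_case():
    return _build_recursion_gene()


class TestRecursion:
    def test_depth0_unchanged_and_depth1_adds_twin(self, recursion_case):
        gene, b_iv, c_iv = recursion_case
        r0 = search_transcript(gene, SearchParams(max_recursion_depth=0))
        m0 = members_of(r0, 1)
        assert b_iv in m0 and c_iv not in m0
        r1 = search_transcript(gene, SearchParams(max_recursion_depth=1))
        m1 = members_of(r1, 1)
        assert c_iv in m1
        (c1,) = [c for c in r1.clusters if c.query_exon_index == 1]
        depth_by_iv = {(m.start, m.end): m.depth for m in c1.members}
        assert depth_by_iv[c_iv] == 1

    def test_depth_monotonicity(self, recursion_case):
        gene, _, _ = recursion_case
        sets = []
        for depth in (0, 1, 2, 3):
            r = search_transcript(gene, SearchParams(max_recursion_depth=depth))
            sets.append(members_of(r, 1))
        assert sets[0] <= sets[1] <= sets[2] <= sets[3]

    def test_depth0_is_default(self, recursion_case):
        gene, _, _ = recursion_case
        cluster = search_exon(gene, 1, SearchParams())
        expanded = recursive_expand(gene, cluster, SearchParams())
        assert {(m.start, m.end) for m in expanded.members} == {
            (m.start, m.end) for m in cluster.members
        }


class TestSelfConsistency:
    def test_candidate_as_query_refinds_original(self):
        spec = FixtureSpec(seed=16, n_exons=3, exon_aa_lengths=(20, 30, 22),
                           intron_lengths=(150, 200),
                           implants=((1, 1, 0.0, 0.0),))
        _, gene, truth = random_gene(spec)
        alt = (int(truth.iloc[0]["start"]), int(truth.iloc[0]["end"]))
        orig = (gene.exons[1].start, gene.exons[1].end)
        swapped_coords = sorted(
            alt if (e.start, e.end) == orig else (e.start, e.end)
            for e in gene.exons
        )
        gene2 = derive_gene_structure(swapped_coords, gene.sequence)
        qi = [i for i, c in enumerate(swapped_coords) if c == alt][0]
        cluster = search_exon(gene2, qi, SearchParams())
        found = {(m.start, m.end): m.relative_score for m in cluster.candidates}
        assert orig in found
        assert found[orig] == pytest.approx(1.0)


class TestGroupPattern:
    def test_tandem_array_flagged(self):
        spec = FixtureSpec(seed=17, n_exons=3, exon_aa_lengths=(20, 28, 22),
                           intron_lengths=(100, 120))
        _, base, _ = random_gene(spec)
        _, gene, _ = make_tandem_array(base, n_copies=2, divergence=0.0, seed=17)
        params = SearchParams(search_all_introns=True, search_updownstream=True)
        result = search_transcript(gene, params)
        assert len(result.clusters) == 3
        assert {c.classification for c in result.clusters} == {"group_pattern"}

    def test_single_copy_no_group(self):
        spec = FixtureSpec(seed=17, n_exons=3, exon_aa_lengths=(20, 28, 22),
                           intron_lengths=(100, 120))
        _, base, _ = random_gene(spec)
        _, gene, _ = make_tandem_array(base, n_copies=1, divergence=0.0, seed=17)
        params = SearchParams(search_all_introns=True, search_updownstream=True)
        result = search_transcript(gene, params)
        assert not any(c.classification == "group_pattern" for c in result.clusters)

    def test_trans_spliced_misleading_then_flagged(self):
        _, gene, truth = make_trans_spliced_fixture(seed=18)
        b_first = truth[(truth.label == "B0")].iloc[0]
        b_iv = (int(b_first["start"]), int(b_first["end"]))
        # surrounding-introns search proposes the first group-B exon as a
        # seemingly mutually exclusive partner of the first group-A exon
        r_sur = search_transcript(gene, SearchParams())
        (c1,) = [c for c in r_sur.clusters if c.query_exon_index == 1]
        assert b_iv in {(m.start, m.end) for m in c1.candidates}
        assert c1.classification == "internal_mxe"
        # the all-introns search reveals the parallel group
        r_all = search_transcript(gene, SearchParams(search_all_introns=True))
        flagged = {c.query_exon_index for c in r_all.clusters
                   if c.classification == "group_pattern"}
        assert {1, 2, 3} <= flagged

    def test_simple_mxe_not_flagged(self):
        spec = FixtureSpec(seed=19, n_exons=3, exon_aa_lengths=(20, 30, 22),
                           intron_lengths=(150, 200),
                           implants=((1, 2, 0.0, 0.0),))
        _, gene, _ = random_gene(spec)
        params = SearchParams(search_all_introns=True, search_updownstream=True)
        result = search_transcript(gene, params)
        assert not any(c.classification == "group_pattern" for c in result.clusters)
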