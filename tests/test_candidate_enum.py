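"""Candidate enumeration: site finding, constraint pairing, oracle equivalence."""

import numpy as np
import pytest

from mxefinder.candidates import (
    SearchRegion,
    enumerate_candidates,
    enumerate_first_exon_candidates,
    enumerate_last_exon_candidates,
    enumerate_with_context,
    find_acceptor_sites,
    find_donor_sites,
    _frame_context,
)
from mxefinder.search import SearchParams
from mxefinder.splice import acceptor_targets, donor_targets

from conftest import build_gene
from instances import make_enum_case
from oracles import brute_force_enumerate


class TestSiteFinding:
    def test_acceptor_scan(self):
        region = SearchRegion(0, 8, "other_intron")
        assert find_acceptor_sites("GTCCAGTT", region, {"AG"}) == [6]

    def test_overlapping_acceptors_kept(self):
        region = SearchRegion(0, 6, "other_intron")
        assert find_acceptor_sites("AGAGAG", region, {"AG"}) == [2, 4, 6]

    def test_no_acceptor(self):
        region = SearchRegion(0, 4, "other_intron")
        assert find_acceptor_sites("CCCC", region, {"AG"}) == []

    def test_donor_scan(self):
        region = SearchRegion(0, 6, "other_intron")
        assert find_donor_sites("AAGTAA", region, {"GT", "GC", "GG"}) == [2]

    def test_overlapping_donors_kept(self):
        region = SearchRegion(0, 4, "other_intron")
        assert find_donor_sites("GGGG", region, {"GT", "GC", "GG"}) == [0, 1, 2]

    def test_margins_drop_boundary_sites(self):
        region = SearchRegion(0, 6, "other_intron")
        assert find_acceptor_sites("AGAGAG", region, {"AG"}, min_new_intron_length=4) == [4, 6]
        region2 = SearchRegion(0, 4, "other_intron")
        assert find_donor_sites("GGGG", region2, {"GT", "GC", "GG"},
                                min_new_intron_length=4) == [0]


class TestEnumerateHandExamples:
    def test_single_compatible_interval(self):
        # downstream intron harbours exactly one frame-compatible 9-nt copy
        intron = "GTAAACAGATGGCTGAAGTTTTTTTAG"
        _, gene = build_gene(
            ["ATGGGTCCTCAT", "ATGGCTGAG", "TCCGCTCAT"],
            ["GT" + "A" * 20 + "AG", intron],
        )
        params = SearchParams(allowed_length_difference=0, min_exon_length=1)
        intr = gene.introns[1]
        region = SearchRegion(intr.start, intr.end, "downstream_intron")
        cands = enumerate_candidates(gene, 1, region, params)
        rel = [(c.start - intr.start, c.end - intr.start) for c in cands]
        assert rel == [(8, 17)]
        body = gene.sequence.residues[cands[0].start : cands[0].end]
        assert body == "ATGGCTGAA"

    def test_length_mismatch_yields_nothing(self):
        intron = "GTAAACAGATGGCTGAAGTTTTTTTAG"
        _, gene = build_gene(
            ["ATGGGTCCTCAT", "ATGGCTGAGCCT", "TCCGCTCAT"],
            ["GT" + "A" * 20 + "AG", intron],
        )
        params = SearchParams(allowed_length_difference=0, min_exon_length=1)
        intr = gene.introns[1]
        region = SearchRegion(intr.start, intr.end, "downstream_intron")
        assert enumerate_candidates(gene, 1, region, params) == []

    def test_short_query_exon_not_searched(self):
        _, gene = build_gene(
            ["ATGGGTCCTCAT", "ATGGCTGAG", "TCCGCTCAT"],
            ["GT" + "A" * 20 + "AG", "GT" + "C" * 20 + "AG"],
        )
        params = SearchParams()  # default min_exon_length 15 aa; query is 3 aa
        intr = gene.introns[1]
        region = SearchRegion(intr.start, intr.end, "downstream_intron")
        assert enumerate_candidates(gene, 1, region, params) == []

    def test_first_exon_atg_anchored(self):
        upstream = "CCATGGCTGAAGTCC"
        _, gene = build_gene(
            ["ATGTTACGTGCT", "TCCGCTCAT"],
            ["GT" + "A" * 20 + "AG"],
            flank_up=upstream,
        )
        params = SearchParams(allowed_length_difference=1, min_exon_length=1)
        region = SearchRegion(0, len(upstream), "upstream_region")
        cands = enumerate_first_exon_candidates(gene, region, params)
        assert [(c.start, c.end) for c in cands] == [(2, 11)]
        assert gene.sequence.residues[2:11] == "ATGGCTGAA"

    def test_first_exon_region_without_atg(self):
        _, gene = build_gene(
            ["ATGTTACGTGCT", "TCCGCTCAT"],
            ["GT" + "A" * 20 + "AG"],
            flank_up="CCCCCCGGGTTCCC",
        )
        params = SearchParams(allowed_length_difference=1, min_exon_length=1)
        region = SearchRegion(0, 14, "upstream_region")
        assert enumerate_first_exon_candidates(gene, region, params) == []

    def test_last_exon_stop_anchored(self):
        embedded = "CCAGGCTGAAGAGTAACC"
        intron = "GT" + "A" * 8 + embedded + "T" * 8 + "AG"
        _, gene = build_gene(["ATGGGTCCTCAT", "GATTACGCT"], [intron])
        params = SearchParams(allowed_length_difference=0, min_exon_length=1)
        off = gene.introns[0].start + 2 + 8
        region = SearchRegion(off, off + len(embedded), "upstream_intron")
        cands = enumerate_last_exon_candidates(gene, region, params)
        rel = [(c.start - off, c.end - off) for c in cands]
        assert rel == [(4, 13)]
        assert gene.sequence.residues[cands[0].start : cands[0].end] == "GCTGAAGAG"
        stop = gene.sequence.residues[cands[0].end : cands[0].end + 3]
        assert stop == "TAA"

    def test_last_exon_no_stop_in_region(self):
        intron = "GT" + "AGGGGCGGGGCGGGGC" * 2 + "AG"
        _, gene = build_gene(["ATGGGTCCTCAT", "GATTACGCT"], [intron])
        params = SearchParams(allowed_length_difference=0, min_exon_length=1)
        intr = gene.introns[0]
        region = SearchRegion(intr.start, intr.end, "upstream_intron")
        assert enumerate_last_exon_candidates(gene, region, params) == []


class TestOracleEquivalence:
    def _run_case(self, gene, qi, bounds, params, anchors, targets):
        region = SearchRegion(bounds[0], bounds[1], "other_intron")
        ctx = _frame_context(gene, qi, params)
        got = {
            (c.start, c.end)
            for c in enumerate_with_context(
                gene, qi, region, params, ctx, anchors[0], anchors[1]
            )
        }
        exon = gene.exons[qi]
        expected = brute_force_enumerate(
            gene.sequence.residues,
            bounds[0],
            bounds[1],
            targets[0] or set(),
            targets[1] or set(),
            exon.length,
            params.allowed_length_difference,
            params.min_new_intron_length,
            start_anchor=anchors[0],
            end_anchor=anchors[1],
        )
        expected.discard((exon.start, exon.end))
        return got, expected

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(150):
            case = make_enum_case(rng)
            got, expected = self._run_case(*case)
            assert got == expected

    def test_every_interval_satisfies_constraints(self):
        rng = np.random.default_rng(987)
        for _ in range(40):
            gene, qi, bounds, params, anchors, _ = make_enum_case(rng)
            region = SearchRegion(bounds[0], bounds[1], "other_intron")
            ctx = _frame_context(gene, qi, params)
            res = gene.sequence.residues
            exon = gene.exons[qi]
            for c in enumerate_with_context(
                gene, qi, region, params, ctx, anchors[0], anchors[1]
            ):
                assert (c.end - c.start - exon.length) % 3 == 0
                assert abs(c.end - c.start - exon.length) <= 3 * params.allowed_length_difference
                assert "N" not in res[c.start : c.end]
                if anchors[0] == "splice":
                    assert res[c.start - 2 : c.start] in acceptor_targets(
                        gene.introns[qi - 1].donor
                    )
                    assert c.start - region.start >= params.min_new_intron_length
                else:
                    assert res[c.start : c.start + 3] == "ATG"
                if anchors[1] == "splice":
                    assert res[c.end : c.end + 2] in donor_targets(
                        gene.introns[qi].acceptor
                    )
                    assert region.end - c.end >= params.min_new_intron_length
                else:
                    assert res[c.end : c.end + 3] in ("TAA", "TAG", "TGA")

    def test_shrinking_length_window_never_adds(self):
        rng = np.random.default_rng(555)
        for _ in range(25):
            gene, qi, bounds, params, anchors, _ = make_enum_case(rng)
            region = SearchRegion(bounds[0], bounds[1], "other_intron")
            ctx_wide = _frame_context(gene, qi, params)
            sets = []
            for ald in (20, 5, 0):
                params.allowed_length_difference = ald
                ctx = _frame_context(gene, qi, params)
                sets.append(
                    {
                        (c.start, c.end)
                        for c in enumerate_with_context(
                            gene, qi, region, params, ctx, anchors[0], anchors[1]
                        )
                    }
                )
            assert sets[2] <= sets[1] <= sets[0]
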