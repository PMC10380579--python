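"""Poly(A)/CCA tail calling, transcript models, boundary classes."""

import numpy as np
import pytest

from mitohairpin.coverage import AlignmentRecord, CoverageTrack, coverage_tracks, end_ratio
from mitohairpin.genome import CircularSequence, GeneRecord, GeneTable, revcomp
from mitohairpin.transcripts import (
    PolyASite,
    TailObservation,
    annotate_sites,
    build_transcript_models,
    call_polya_sites,
    classify_boundaries,
    complete_stop_codon,
    detect_tails,
)


def toy_genome(seq):
    return CircularSequence("toy", seq)


class TestDetectTails:
    def test_plus_strand_tail(self):
        # read aligned 1..10, clip AAAAA, reference continues with C's
        genome = toy_genome("GTGTGTGTGT" + "C" * 20)
        read = AlignmentRecord("r", 1, 10, "+", right_clip_seq="AAAAA")
        (obs,) = detect_tails([read], genome, min_tail=4)
        assert (obs.site, obs.strand, obs.tail_a_len, obs.has_cca_prefix) == (
            10, "+", 5, False
        )

    def test_cca_prefixed_tail(self):
        genome = toy_genome("GTGTGTGTGT" + "T" * 20)
        read = AlignmentRecord("r", 1, 10, "+", right_clip_seq="CCAAAAA")
        (obs,) = detect_tails([read], genome, min_tail=4)
        assert obs.has_cca_prefix and obs.tail_a_len == 4

    def test_templated_a_run_is_not_a_tail(self):
        genome = toy_genome("GTGTGTGTGT" + "AAAA" + "C" * 16)
        read = AlignmentRecord("r", 1, 10, "+", right_clip_seq="AAAA")
        assert detect_tails([read], genome, min_tail=4) == []

    def test_minus_strand_tail_mirrors(self):
        # minus-strand transcript: 3' end at the read's leftmost base; the
        # genomic continuation upstream must not read as T-run (A on -)
        genome = toy_genome("C" * 10 + "GTGTGTGTGT" + "C" * 10)
        read = AlignmentRecord("r", 11, 10, "-", left_clip_seq="TTTTT")
        (obs,) = detect_tails([read], genome, min_tail=4)
        assert (obs.site, obs.strand, obs.tail_a_len) == (11, "-", 5)

    def test_short_tail_below_threshold_ignored(self):
        genome = toy_genome("GTGTGTGTGT" + "C" * 20)
        read = AlignmentRecord("r", 1, 10, "+", right_clip_seq="AAA")
        assert detect_tails([read], genome, min_tail=4) == []

    def test_non_a_clip_ignored(self):
        genome = toy_genome("GTGTGTGTGT" + "C" * 20)
        read = AlignmentRecord("r", 1, 10, "+", right_clip_seq="AAGAA")
        assert detect_tails([read], genome, min_tail=4) == []


class TestCallSites:
    def _obs(self, site, strand="+", cca=False, rid=None):
        return TailObservation(rid or f"r{site}", site, strand, "AAAAA", cca, 5)

    def test_identical_positions_merge(self):
        tails = [self._obs(50, rid=f"r{i}") for i in range(5)]
        (site,) = call_polya_sites(tails, min_support=2)
        assert (site.site, site.n_reads) == (50, 5)

    def test_modal_tie_breaks_to_smaller_coordinate(self):
        tails = [self._obs(50, rid="a"), self._obs(51, rid="b")]
        (site,) = call_polya_sites(tails, min_support=2, cluster_window=2)
        assert site.site == 50

    def test_min_support_filters(self):
        assert call_polya_sites([self._obs(50)], min_support=2) == []

    def test_strands_do_not_merge(self):
        tails = [self._obs(50, "+", rid="a"), self._obs(50, "-", rid="b"),
                 self._obs(50, "+", rid="c"), self._obs(50, "-", rid="d")]
        sites = call_polya_sites(tails, min_support=2)
        assert sorted((s.site, s.strand) for s in sites) == [(50, "+"), (50, "-")]

    def test_cca_fraction(self):
        tails = [self._obs(50, cca=True, rid="a"), self._obs(50, cca=False, rid="b")]
        (site,) = call_polya_sites(tails, min_support=2)
        assert site.cca_fraction == 0.5

    def test_synthetic_sites_recovered_exactly(self, sim_bundle, sim_rna_records):
        _, genome, _, _, _, truth = sim_bundle
        tails = detect_tails(sim_rna_records, genome)
        called = call_polya_sites(tails, min_support=2, cluster_window=3)
        truth_set = {(s.site, s.strand) for s in truth.cleavage_sites}
        called_set = {(s.site, s.strand) for s in called}
        assert called_set == truth_set
        cca_called = {s.site for s in called if s.cca_fraction > 0}
        assert cca_called == set(truth.cca_sites)


class TestAnnotateSites:
    def _table(self):
        return GeneTable("toy", 1000, [
            GeneRecord("cox2", "+", 1, 300),
            GeneRecord("trnK", "+", 311, 370),
            GeneRecord("trnD", "+", 381, 440),
            GeneRecord("nad1", "-", 600, 900),
        ])

    @pytest.mark.parametrize(
        "site,strand,expected",
        [
            (300, "+", "immediate"),
            (306, "+", "short_utr"),
            (370, "+", "one_trna"),
            (440, "+", "two_trna"),
            (500, "+", "other"),
            (600, "-", "immediate"),
        ],
    )
    def test_utr_classes(self, site, strand, expected):
        s = PolyASite(site, strand, 3, 0.0)
        annotate_sites([s], self._table())
        assert s.utr_class == expected
        assert s.context_gene == ("nad1" if strand == "-" else "cox2")


class TestStopCompletion:
    def test_incomplete_t_completed(self):
        # 10-base ORF (3k+1) ending in T, polyadenylated at its last base
        orf = "ATGAAAAAAT"
        genome = toy_genome(orf + "G" * 20)
        gene = GeneRecord("nad3", "+", 1, 10)
        site = PolyASite(10, "+", 5, 0.0)
        assert complete_stop_codon(gene, site, genome) == "completed_T"

    def test_complete_taa(self):
        orf = "ATGAAATAA"
        genome = toy_genome(orf + "G" * 21)
        gene = GeneRecord("x", "+", 1, 9)
        assert complete_stop_codon(gene, PolyASite(9, "+", 5, 0.0), genome) == "complete"

    def test_inconsistent_end(self):
        orf = "ATGAAAAAGG"  # 3k+1 not ending T... 10 % 3 == 1, ends G
        genome = toy_genome(orf + "C" * 20)
        gene = GeneRecord("x", "+", 1, 10)
        assert complete_stop_codon(gene, PolyASite(10, "+", 5, 0.0), genome) == "inconsistent"

    def test_completed_ta(self):
        orf = "ATGAAATA"  # 8 = 3k+2, ends TA
        genome = toy_genome(orf + "G" * 22)
        gene = GeneRecord("x", "+", 1, 8)
        assert complete_stop_codon(gene, PolyASite(8, "+", 5, 0.0), genome) == "completed_TA"

    def test_minus_strand_orf(self):
        orf = "ATGAAAAAAT"  # completed_T, on the minus strand
        genome = toy_genome("G" * 10 + revcomp(orf) + "G" * 10)
        gene = GeneRecord("x", "-", 11, 20)
        assert complete_stop_codon(gene, PolyASite(11, "-", 5, 0.0), genome) == "completed_T"

    def test_non_pcg_rejected(self):
        genome = toy_genome("A" * 30)
        with pytest.raises(ValueError):
            complete_stop_codon(GeneRecord("trnK", "+", 1, 10), PolyASite(10, "+", 2, 0.0), genome)


class TestTranscriptModels:
    def _table(self):
        return GeneTable("toy", 2000, [
            GeneRecord("nad3", "+", 1, 300),
            GeneRecord("trnA", "+", 310, 370),
            GeneRecord("trnR", "+", 380, 440),
            GeneRecord("nad6", "+", 500, 800),
            GeneRecord("cytb", "+", 810, 1200),
            GeneRecord("nad1", "-", 1300, 1800),
        ])

    def test_sites_after_every_pcg_give_monocistrons(self):
        sites = [PolyASite(300, "+", 5, 0), PolyASite(800, "+", 5, 0),
                 PolyASite(1200, "+", 5, 0), PolyASite(1300, "-", 5, 0)]
        models = build_transcript_models(self._table(), sites)
        assert all(m.cistronic_class == "mono" for m in models)
        assert sorted(m.cistrons[0] for m in models) == ["cytb", "nad1", "nad3", "nad6"]

    def test_missing_site_fuses_bicistron(self):
        sites = [PolyASite(300, "+", 5, 0), PolyASite(1200, "+", 5, 0),
                 PolyASite(1300, "-", 5, 0)]
        models = build_transcript_models(self._table(), sites)
        bi = next(m for m in models if m.cistronic_class == "bi")
        assert bi.cistrons == ["nad6", "cytb"]

    def test_terminal_trnas_recorded(self):
        sites = [PolyASite(440, "+", 5, 0), PolyASite(800, "+", 5, 0),
                 PolyASite(1200, "+", 5, 0), PolyASite(1300, "-", 5, 0)]
        models = build_transcript_models(self._table(), sites)
        nad3 = next(m for m in models if m.cistrons == ["nad3"])
        assert nad3.terminal_trnas == ["trnA", "trnR"]
        assert nad3.three_end.site == 440

    def test_every_pcg_in_exactly_one_model(self, sim_bundle, sim_rna_records):
        _, genome, table, _, _, _ = sim_bundle
        tails = detect_tails(sim_rna_records, genome)
        sites = call_polya_sites(tails)
        models = build_transcript_models(table, sites)
        pcgs = sorted(g.name for g in table.by_class("PCG"))
        in_models = sorted(n for m in models for n in m.cistrons)
        assert in_models == pcgs

    def test_no_site_in_span_warns_and_leaves_open_end(self, caplog):
        table = GeneTable("toy", 2000, [GeneRecord("cox1", "+", 1, 300)])
        models = build_transcript_models(table, [], max_span=500)
        assert models[0].three_end is None


class TestBoundaryClassification:
    def _table(self):
        return GeneTable("toy", 3000, [
            GeneRecord("pcgA", "+", 1, 500),
            GeneRecord("trnX", "+", 520, 580),
            GeneRecord("pcgB", "+", 600, 1100),
            GeneRecord("pcgC", "+", 1150, 1700),
            GeneRecord("pcgD", "+", 1750, 2300),
        ])

    def _flat_track(self, L=3000, depth=50):
        depth_arr = np.full(L, depth, dtype=np.int64)
        return CoverageTrack(depth_arr, np.zeros(L, dtype=np.int64),
                             np.zeros(L, dtype=np.int64))

    def test_three_way_classification(self):
        sites = [PolyASite(580, "+", 5, 0),    # after the tRNA: punctuated
                 PolyASite(1100, "+", 5, 0)]   # between ORFs, no tRNA
        track = self._flat_track()
        bounds = classify_boundaries(self._table(), sites, None, track)
        by_pair = {(b.upstream, b.downstream): b.boundary_class for b in bounds}
        assert by_pair[("pcgA", "pcgB")] == "trna_punctuated"
        assert by_pair[("pcgB", "pcgC")] == "non_trna_cleavage"
        assert by_pair[("pcgC", "pcgD")] == "no_cleavage"

    def test_flat_depth_has_no_gradient(self):
        bounds = classify_boundaries(self._table(), [], None, self._flat_track())
        assert all(b.gradient == "none" for b in bounds)

    def test_planted_reverse_gradient_detected(self, rng):
        # depth falls from the upstream ORF's 3' end across the inter-ORF
        # block: the reverse-processing signature
        L = 3000
        depth = np.full(L, 50.0)
        depth[500:599] = np.linspace(200, 50, 99)
        depth += rng.normal(0, 2, L)
        track = CoverageTrack(np.maximum(depth, 0).astype(np.int64),
                              np.zeros(L, dtype=np.int64), np.zeros(L, dtype=np.int64))
        bounds = classify_boundaries(self._table(), [], None, track)
        b = next(x for x in bounds if (x.upstream, x.downstream) == ("pcgA", "pcgB"))
        assert b.gradient == "reverse"

    def test_planted_forward_gradient_detected(self, rng):
        L = 3000
        depth = np.full(L, 50.0)
        depth[500:599] = np.linspace(50, 200, 99)
        depth += rng.normal(0, 2, L)
        track = CoverageTrack(np.maximum(depth, 0).astype(np.int64),
                              np.zeros(L, dtype=np.int64), np.zeros(L, dtype=np.int64))
        bounds = classify_boundaries(self._table(), [], None, track)
        b = next(x for x in bounds if (x.upstream, x.downstream) == ("pcgA", "pcgB"))
        assert b.gradient == "forward"


class TestStrandSymmetry:
    def test_mirrored_alignments_give_mirrored_sites(self):
        L = 40
        fwd_genome = toy_genome("GTGTGTGTGT" + "C" * 30)
        read = AlignmentRecord("r", 1, 10, "+", right_clip_seq="AAAAA")
        (fwd_obs,) = detect_tails([read], fwd_genome, min_tail=4)

        rev_genome = fwd_genome.reverse_complement()
        # the same physical read, seen on the reverse-complemented genome:
        # aligned block moves to the other end, strand flips, clip side flips
        mirrored = AlignmentRecord(
            "r", L - 10 + 1, 10, "-", left_clip_seq=revcomp("AAAAA")
        )
        (rev_obs,) = detect_tails([mirrored], rev_genome, min_tail=4)
        assert rev_obs.site == L - fwd_obs.site + 1
        assert rev_obs.strand == "-"
        assert rev_obs.tail_a_len == fwd_obs.tail_a_len
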