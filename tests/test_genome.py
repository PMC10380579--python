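"""Circular-genome model: parsing, composition, complement, rotation."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitohairpin as mh
from mitohairpin.genome import (
    CircularSequence,
    GeneRecord,
    GeneTable,
    IntergenicSegment,
    at_skew,
    composition,
    gc_skew,
    intergenic_complement,
    read_gene_table,
    rotate,
    strand_partition,
    validate_annotation,
)


def toy_table(records, L=100):
    return GeneTable("toy", L, records)


class TestGeneTable:
    def test_bundled_annotation_parses_to_37_genes(self, p_table):
        assert len(p_table) == 37
        assert p_table.class_counts() == {"PCG": 13, "tRNA": 22, "rRNA": 2}

    def test_strand_partition_sizes(self, p_table):
        plus, minus = strand_partition(p_table)
        assert (len(plus), len(minus)) == (25, 12)
        assert {r.name for r in plus} | {r.name for r in minus} == {
            r.name for r in p_table
        }

    def test_strand_partition_is_order_independent(self, p_table):
        shuffled = list(p_table.records)
        random.Random(3).shuffle(shuffled)
        plus, minus = strand_partition(toy_table(shuffled, p_table.genome_length))
        assert (len(plus), len(minus)) == (25, 12)

    def test_gene_lengths_match_published_column(self, p_table):
        L = p_table.genome_length
        assert p_table.get("cox1").length(L) == 1533
        assert p_table.get("nad3").length(L) == 336
        assert p_table.get("rrnL").length(L) == 1069

    def test_origin_spanning_record_length(self):
        rec = GeneRecord("g", "+", 95, 5)
        assert rec.length(100) == 11

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            toy_table([GeneRecord("a", "+", 1, 10), GeneRecord("a", "+", 20, 30)])

    def test_empty_annotation_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert len(read_gene_table(p)) == 0

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tstrand\tstart\tstop\nfoo\t+\tnotanumber\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gene_table(p)

    def test_tsv_round_trip(self, p_table, tmp_path):
        out = tmp_path / "genes.tsv"
        p_table.to_tsv(out)
        back = read_gene_table(out, genome_id=p_table.genome_id,
                               genome_length=p_table.genome_length)
        assert [(r.name, r.strand, r.start, r.stop, r.gene_class)
                for r in back] == [
            (r.name, r.strand, r.start, r.stop, r.gene_class) for r in p_table
        ]

    def test_gff3_round_trip(self, p_table, tmp_path):
        out = tmp_path / "genes.gff3"
        p_table.to_gff3(out)
        back = read_gene_table(out, dialect="gff3")
        assert back.genome_length == p_table.genome_length
        assert [(r.name, r.strand, r.start, r.stop) for r in back] == [
            (r.name, r.strand, r.start, r.stop) for r in p_table
        ]


class TestComposition:
    def test_balanced_sequence_has_zero_skews(self):
        stats = composition(CircularSequence("t", "ATGC"))
        assert stats.at_skew == 0 and stats.gc_skew == 0

    def test_skew_formulas_on_percentages(self):
        assert at_skew(33, 40) == pytest.approx(-0.096, abs=5e-4)
        assert gc_skew(12, 15) == pytest.approx(-0.11, abs=5e-3)

    def test_reverse_complement_negates_skews(self, rng):
        seq = CircularSequence("t", "".join(rng.choice(list("ACGT"), size=400)))
        fwd = composition(seq)
        rev = composition(seq.reverse_complement())
        assert rev.pct_A == pytest.approx(fwd.pct_T)
        assert rev.pct_G == pytest.approx(fwd.pct_C)
        assert rev.at_skew == pytest.approx(-fwd.at_skew)
        assert rev.gc_skew == pytest.approx(-fwd.gc_skew)

    def test_n_excluded_from_denominator(self):
        stats = composition(CircularSequence("t", "AANN"))
        assert stats.n_bases == 2 and stats.pct_A == 100.0

    def test_subset_composition(self):
        seq = CircularSequence("t", "GGGGAAAATTTT")
        stats = composition(seq, [GeneRecord("g", "+", 5, 12)])
        assert stats.pct_G == 0 and stats.pct_A == 50

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            CircularSequence("t", "ACGTR")

    def test_empty_subset_errors(self):
        seq = CircularSequence("t", "ACGT")
        with pytest.raises(ValueError):
            composition(seq, [])


class TestIntergenicComplement:
    def test_hand_enumerated_toy(self):
        table = toy_table(
            [GeneRecord("a", "+", 1, 40), GeneRecord("b", "+", 61, 90)]
        )
        segs = intergenic_complement(table)
        assert [(s.start, s.stop, s.length) for s in segs] == [
            (41, 60, 20), (91, 100, 10)
        ]
        assert segs[0].left_gene == "a" and segs[0].right_gene == "b"

    def test_full_circle_gene_gives_empty_complement(self):
        table = toy_table([GeneRecord("a", "+", 1, 100)])
        assert intergenic_complement(table) == []

    def test_origin_spanning_segment_reported_once(self):
        table = toy_table([GeneRecord("a", "+", 10, 90)])
        segs = intergenic_complement(table)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].stop, segs[0].length) == (91, 9, 19)

    def test_bundled_table_largest_segment(self, p_table):
        segs = intergenic_complement(p_table)
        largest = max(segs, key=lambda s: s.length)
        assert largest.length == 175
        assert (largest.left_gene, largest.right_gene) == ("trnL2", "cox1")
        assert (largest.start, largest.stop) == (13848, 9)

    @given(st.lists(
        st.tuples(st.integers(1, 200), st.integers(1, 200)),
        min_size=1, max_size=8,
    ))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_complement_plus_union_covers_circle(self, intervals):
        L = 200
        records = [
            GeneRecord(f"g{i}", "+", a, b) for i, (a, b) in enumerate(intervals)
        ]
        table = toy_table(records, L)
        segs = intergenic_complement(table)
        covered = np.zeros(L, dtype=bool)
        for r in records:
            s0, s1 = r.interval(L)
            covered[np.arange(s0, s1) % L] = True
        assert sum(s.length for s in segs) + covered.sum() == L


class TestValidation:
    def test_published_nad6_cytb_overlap(self, p_table):
        rep = validate_annotation(p_table)
        pair = next(a for a in rep.adjacencies if a.left == "nad6")
        assert (pair.right, pair.relation, pair.n_bases) == ("cytb", "overlap", 50)

    def test_totals_surface_annotation_inconsistencies(self, p_table):
        # the complement of the printed coordinates; companion published
        # totals (624 bp / 22 segments) disagree and must stay visible
        rep = validate_annotation(p_table)
        assert rep.n_intergenic_segments == 23
        assert rep.total_intergenic == 631
        assert "intergenic: 631 bp in 23 segments" in rep.summary()

    def test_abut_and_gap_labels(self):
        table = toy_table(
            [GeneRecord("a", "+", 1, 10), GeneRecord("b", "+", 11, 20),
             GeneRecord("c", "+", 26, 90)]
        )
        rep = validate_annotation(table)
        rels = {(a.left, a.right): (a.relation, a.n_bases) for a in rep.adjacencies}
        assert rels[("a", "b")] == ("abut", 0)
        assert rels[("b", "c")] == ("gap", 5)
        assert rep.n_overlaps == 0

    def test_pcg_frame_remainders_flagged(self):
        table = toy_table([GeneRecord("nad3", "+", 1, 10)])  # 10 % 3 == 1
        rep = validate_annotation(table)
        assert rep.frame_flags == {"nad3": 1}


class TestRotate:
    def _toy(self):
        seq = CircularSequence("t", "ACGTACGTAC" * 10)
        table = toy_table(
            [GeneRecord("a", "+", 95, 5), GeneRecord("b", "-", 20, 50)]
        )
        return seq, table

    def test_rotate_by_one_is_identity(self):
        seq, table = self._toy()
        s2, t2 = rotate(seq, table, 1)
        assert s2.seq == seq.seq
        assert [(r.start, r.stop) for r in t2] == [(r.start, r.stop) for r in table]

    def test_rotate_then_back_restores(self):
        seq, table = self._toy()
        s2, t2 = rotate(seq, table, 37)
        s3, t3 = rotate(s2, t2, 100 - 37 + 2)
        assert s3.seq == seq.seq
        assert [(r.start, r.stop) for r in t3] == [(r.start, r.stop) for r in table]

    def test_origin_spanning_gene_lands_at_origin(self):
        seq, table = self._toy()
        _, t2 = rotate(seq, table, 95)
        assert (t2.get("a").start, t2.get("a").stop) == (1, 11)

    def test_rotation_preserves_composition_and_segments(self, p_table, rng):
        seq = CircularSequence(
            "t", "".join(rng.choice(list("ACGT"), size=p_table.genome_length))
        )
        s2, t2 = rotate(seq, p_table, 4_321)
        assert composition(s2).rounded() == composition(seq).rounded()
        before = sorted(s.length for s in intergenic_complement(p_table))
        after = sorted(s.length for s in intergenic_complement(t2))
        assert before == after
        assert [len(x) for x in strand_partition(t2)] == [25, 12]

    def test_out_of_range_origin(self):
        seq, table = self._toy()
        with pytest.raises(ValueError):
            rotate(seq, table, 0)
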