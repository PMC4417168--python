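"""Annotation readers, merge/filter rules, and set reconciliation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intragenic_te import annotations
from intragenic_te.intervals import GenomicInterval, RepeatMaskerHit, TERecord

from conftest import make_te

GFF = """##gff-version 3
Chr1\tsrc\tgene\t100\t3000\t.\t+\t.\tID=G1;biotype=protein-coding
Chr1\tsrc\tmRNA\t100\t3000\t.\t+\t.\tID=G1.1;Parent=G1
Chr1\tsrc\texon\t100\t1000\t.\t+\t.\tID=G1.1.e1;Parent=G1.1
Chr1\tsrc\texon\t2000\t2299\t.\t+\t.\tID=G1.1.e2;Parent=G1.1
Chr1\tsrc\tmRNA\t100\t3000\t.\t+\t.\tID=G1.2;Parent=G1
Chr1\tsrc\texon\t100\t1000\t.\t+\t.\tID=G1.2.e1;Parent=G1.2
Chr1\tsrc\texon\t2000\t2598\t.\t+\t.\tID=G1.2.e2;Parent=G1.2
Chr1\tsrc\tgene\t5000\t5400\t.\t-\t.\tID=G2;biotype=ncRNA
Chr1\tsrc\tmRNA\t5000\t5400\t.\t-\t.\tID=G2.1;Parent=G2
Chr1\tsrc\texon\t5000\t5400\t.\t-\t.\tID=G2.1.e1;Parent=G2.1
Chr1\tsrc\tgene\t7000\t7500\t.\t+\t.\tID=G3;biotype=transposable_element_gene
Chr1\tsrc\tmRNA\t7000\t7500\t.\t+\t.\tID=G3.1;Parent=G3
Chr1\tsrc\texon\t7000\t7500\t.\t+\t.\tID=G3.1.e1;Parent=G3.1
"""


class TestReadGff3Genes:
    def test_longest_isoform_and_introns(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GFF)
        genes = annotations.read_gff3_genes(path)
        g1 = {g.gene_id: g for g in genes}["G1"]
        # exon sums: G1.1 = 901+300=1201, G1.2 = 901+599=1500
        assert g1.longest_transcript_id == "G1.2"
        assert [(-i.length, i.start) for i in g1.introns()] == [(-999, 1001)]
        g2 = {g.gene_id: g for g in genes}["G2"]
        assert g2.introns() == []  # single exon -> no introns

    def test_equal_exon_sums_tie_breaks_to_smaller_id(self, tmp_path):
        gff = GFF.replace("2000\t2598", "2000\t2299")  # make G1.2 equal to G1.1
        path = tmp_path / "genes.gff3"
        path.write_text(gff)
        g1 = {g.gene_id: g for g in annotations.read_gff3_genes(path)}["G1"]
        assert g1.longest_transcript_id == "G1.1"

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nChr1\tsrc\tgene\t100\n")
        with pytest.raises(annotations.GFF3ParseError, match="line 2"):
            annotations.read_gff3_genes(path)


class TestFilterGenes:
    def test_biotype_filter(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GFF)
        genes = annotations.read_gff3_genes(path)
        kept = annotations.filter_genes(genes)
        assert [g.gene_id for g in kept] == ["G1", "G2"]
        assert annotations.filter_genes([]) == []


def brute_force_merge(tes, max_gap):
    """Independent oracle: union-find over the pairwise gap relation."""
    n = len(tes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = tes[i], tes[j]
            if a.interval.chrom != b.interval.chrom or a.family != b.family:
                continue
            gap = max(a.interval.start, b.interval.start) - min(a.interval.end, b.interval.end) - 1
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(tes[i])
    spans = set()
    for members in groups.values():
        spans.add(
            (
                members[0].interval.chrom,
                members[0].family,
                min(m.interval.start for m in members),
                max(m.interval.end for m in members),
            )
        )
    return spans


class TestMergeTeAnnotations:
    def test_gap_boundary_and_families(self):
        a = make_te("A", start=1000, end=1200)
        b = make_te("B", start=1251, end=1400)  # gap exactly 50
        merged = annotations.merge_te_annotations([a, b], max_gap=50)
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (1000, 1400)
        assert merged[0].te_id == "A"
        c = make_te("C", start=1252, end=1400)  # gap 51
        assert len(annotations.merge_te_annotations([a, c], max_gap=50)) == 2
        d = make_te("D", start=1210, end=1400, family="CopiaF1", superfamily="Copia")
        assert len(annotations.merge_te_annotations([a, d], max_gap=50)) == 2

    def test_transitive_chain(self):
        chain = [
            make_te("A", start=1, end=100),
            make_te("B", start=140, end=200),
            make_te("C", start=240, end=300),
        ]
        merged = annotations.merge_te_annotations(chain, max_gap=50)
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (1, 300)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            annotations.merge_te_annotations([], max_gap=-1)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["F1", "F2"]),
                st.integers(1, 500),
                st.integers(1, 120),
            ),
            min_size=1,
            max_size=12,
        ),
        st.integers(0, 60),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_union_find_oracle_and_is_idempotent(self, raw, max_gap):
        tes = [
            make_te(f"T{i}", start=s, end=s + ln - 1, family=f, superfamily="Gypsy")
            for i, (f, s, ln) in enumerate(raw)
        ]
        merged = annotations.merge_te_annotations(tes, max_gap=max_gap)
        got = {
            (t.interval.chrom, t.family, t.interval.start, t.interval.end) for t in merged
        }
        assert got == brute_force_merge(tes, max_gap)
        again = annotations.merge_te_annotations(merged, max_gap=max_gap)
        assert {
            (t.interval.chrom, t.family, t.interval.start, t.interval.end) for t in again
        } == got
        # coverage never shrinks
        covered_in = set()
        for t in tes:
            covered_in.update(range(t.interval.start, t.interval.end + 1))
        covered_out = set()
        for t in merged:
            covered_out.update(range(t.interval.start, t.interval.end + 1))
        assert covered_in <= covered_out


class TestFilterShortTes:
    @pytest.mark.parametrize("length,kept", [(49, False), (50, True), (51, True)])
    def test_boundary(self, length, kept):
        te = make_te("T", start=100, end=100 + length - 1)
        assert bool(annotations.filter_short_tes([te])) is kept

    def test_empty(self):
        assert annotations.filter_short_tes([]) == []


RM_OUT = """   SW   perc perc perc  query     position in query    matching repeat       position in repeat
score   div. del. ins.  sequence  begin end   (left)   repeat   class/family begin end (left)  ID

  500  10.0  0.0  0.0  Chr1  1000  1349  (8000)  +  REP1  LTR/Gypsy  1  350  (150)  1
  400  12.0  0.0  0.0  Chr1  5000  5349  (4000)  C  REP2  DNA/MuDR  (150)  350  1  2
"""


class TestParseRepeatmaskerOut:
    def test_coverage_and_strand_normalization(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(RM_OUT)
        hits = annotations.parse_repeatmasker_out(path)
        assert len(hits) == 2
        plus, minus = hits
        # consensus positions 1..350 of a 500-bp repeat -> 70%
        assert plus.library_repeat_length == 500
        assert plus.hit_coverage_fraction == pytest.approx(0.70)
        # complement orientation gives identical geometry
        assert minus.library_repeat_length == 500
        assert minus.hit_coverage_fraction == pytest.approx(0.70)
        assert minus.interval.strand == "-"

    def test_empty_after_headers(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text("\n".join(RM_OUT.splitlines()[:3]) + "\n")
        assert annotations.parse_repeatmasker_out(path) == []

    def test_unparsable_record_names_line(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text("  500  10.0  0.0  0.0  Chr1  oops\n")
        with pytest.raises(ValueError, match="line 1"):
            annotations.parse_repeatmasker_out(path)


def _hit(length=200, coverage=0.8, cls="LTR/Gypsy", start=1000):
    lib = int(round(length / coverage))
    return RepeatMaskerHit(
        interval=GenomicInterval("Chr1", start, start + length - 1, "+"),
        repeat_name="R",
        repeat_class=cls,
        library_repeat_length=lib,
        hit_coverage_fraction=length / lib,
    )


class TestFilterRepeatmaskerHits:
    @pytest.mark.parametrize(
        "hit,kept",
        [
            (_hit(length=99), False),
            (_hit(length=100), True),
            (_hit(length=200, coverage=0.69), False),
            (_hit(length=210, coverage=0.70), True),
            (_hit(cls="Simple_repeat"), False),
            (_hit(cls="Satellite/centr"), False),
            (_hit(cls="Low_complexity"), False),
        ],
    )
    def test_screens(self, hit, kept):
        assert bool(annotations.filter_repeatmasker_hits([hit])) is kept


class TestIntersectTeSets:
    def test_single_bp_overlap_retained(self):
        te = make_te("T", start=100, end=200)
        hit = _hit(length=101, start=200)
        out = annotations.intersect_te_sets([te], [hit])
        assert [t.te_id for t in out] == ["T"]
        assert out[0].source == "reconciled"
        assert (out[0].interval.start, out[0].interval.end) == (100, 200)

    def test_non_overlapping_dropped_and_multihit_once(self):
        te = make_te("T", start=100, end=200)
        far = _hit(length=120, start=5000)
        assert annotations.intersect_te_sets([te], [far]) == []
        two = [_hit(length=120, start=90), _hit(length=120, start=150)]
        assert len(annotations.intersect_te_sets([te], two)) == 1

    def test_chrom_mismatch_warns(self, caplog):
        te = make_te("T", chrom="Chr2", start=100, end=200)
        with caplog.at_level("WARNING"):
            out = annotations.intersect_te_sets([te], [_hit()])
        assert out == []
        assert any("Chr2" in rec.message for rec in caplog.records)


def test_reconciled_set_matches_planted_truth(sim_dir, reconciled_te_set):
    """Full merge -> filter -> intersect round-trip recovers the planted set."""
    _out, _cfg, truth = sim_dir
    expected = truth.te[truth.te["in_final_set"]]
    assert sorted(t.te_id for t in reconciled_te_set) == sorted(expected["te_id"])
    spans = {t.te_id: (t.interval.start, t.interval.end) for t in reconciled_te_set}
    for row in expected.itertuples():
        assert spans[row.te_id] == (row.start, row.end)
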