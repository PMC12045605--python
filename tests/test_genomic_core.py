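"""Interval algebra against brute-force per-base oracles, plus file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cretarget.genomic_core import (
    ChromSizes,
    GenomicInterval,
    intersect,
    merge_intervals,
    overlaps,
    read_bed,
    read_chrom_sizes,
    read_gene_models,
    slop,
    sort_intervals,
    write_bed,
    write_chrom_sizes,
    write_gene_models,
)

from conftest import base_mask, mask_to_runs, oracle_intersect, random_intervals


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestGenomicInterval:
    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            iv("chr1", 100, 100)
        with pytest.raises(ValueError):
            iv("chr1", 200, 100)
        with pytest.raises(ValueError):
            iv("chr1", -5, 10)

    def test_length_and_midpoint(self):
        x = iv("chr1", 10, 20)
        assert len(x) == 10
        assert x.midpoint == 15
        assert str(x) == "chr1:10-20"

    def test_chrom_sizes_validation(self):
        sizes = ChromSizes({"chr1": 1000})
        sizes.validate(iv("chr1", 0, 1000))
        with pytest.raises(ValueError):
            sizes.validate(iv("chr1", 500, 1001))
        with pytest.raises(KeyError):
            sizes.validate(iv("chr9", 0, 10))
        with pytest.raises(ValueError):
            ChromSizes({"chr1": 0})


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 0, 100), ("chr1", 99, 200), True),  # 1-bp overlap
            (("chr1", 0, 100), ("chr1", 100, 200), False),  # half-open adjacency
            (("chr1", 0, 100), ("chr2", 0, 100), False),  # disjoint chromosomes
            (("chr1", 50, 60), ("chr1", 0, 1000), True),  # containment
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlaps(iv(*a), iv(*b)) is expected

    def test_all_pairs_match_base_set_oracle(self, rng):
        ivs = random_intervals(rng, 20, ["chrA"], 2000, max_len=300)
        for a in ivs:
            for b in ivs:
                expected = bool(
                    (base_mask([a], "chrA", 2000) & base_mask([b], "chrA", 2000)).any()
                )
                assert overlaps(a, b) is expected


class TestIntersect:
    def test_half_open_overlap(self):
        assert intersect([iv("chr1", 0, 100)], [iv("chr1", 50, 150)]) == [
            iv("chr1", 50, 100)
        ]

    def test_disjoint_chromosomes_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            out = intersect([iv("chr1", 0, 100)], [iv("chr2", 0, 100)])
        assert out == []
        assert "no shared chromosome" in caplog.text

    def test_matches_per_base_oracle_random(self, rng):
        for _ in range(30):
            a = random_intervals(rng, 50, ["c1", "c2"], 10_000)
            b = random_intervals(rng, 50, ["c1", "c2"], 10_000)
            got = [(x.chrom, x.start, x.end) for x in intersect(a, b)]
            assert got == oracle_intersect(a, b, ["c1", "c2"], 10_000)

    def test_self_intersection_is_merge(self, rng):
        a = random_intervals(rng, 40, ["c1"], 5000)
        merged = [(x.chrom, x.start, x.end) for x in merge_intervals(a)]
        self_int = [(x.chrom, x.start, x.end) for x in intersect(a, a)]
        assert self_int == merged

    def test_commutative_at_base_level(self, rng):
        a = random_intervals(rng, 25, ["c1"], 5000)
        b = random_intervals(rng, 25, ["c1"], 5000)
        assert intersect(a, b) == intersect(b, a)


class TestSlop:
    def test_clamped_at_origin(self):
        sizes = ChromSizes({"chr1": 1000})
        assert slop([iv("chr1", 50, 150)], 100, sizes) == [iv("chr1", 0, 250)]

    def test_clamped_at_chromosome_end(self):
        sizes = ChromSizes({"chr1": 1000})
        assert slop([iv("chr1", 900, 950)], 100, sizes) == [iv("chr1", 800, 1000)]

    def test_zero_flank_is_identity(self, rng):
        sizes = ChromSizes({"c1": 10_000})
        ivs = sort_intervals(random_intervals(rng, 20, ["c1"], 10_000))
        assert slop(ivs, 0, sizes) == ivs

    def test_unknown_chromosome_named_in_error(self):
        with pytest.raises(KeyError, match="chrX"):
            slop([iv("chrX", 0, 10)], 5, ChromSizes({"chr1": 100}))

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            slop([iv("chr1", 0, 10)], -1, ChromSizes({"chr1": 100}))

    @given(
        start=st.integers(0, 5000),
        length=st.integers(1, 500),
        f1=st.integers(0, 200),
        f2=st.integers(0, 200),
    )
    @settings(max_examples=60, deadline=None)
    def test_composition_where_unclamped(self, start, length, f1, f2):
        sizes = ChromSizes({"c": 10_000})
        x = [iv("c", start + 1000, start + 1000 + length)]  # keep clear of 0
        once = slop(slop(x, f1, sizes), f2, sizes)
        combined = slop(x, f1 + f2, sizes)
        if once[0].start > 0 and once[0].end < 10_000:
            assert once == combined


class TestBedIO:
    def test_minimal_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        assert read_bed(p) == [iv("chr1", 0, 100)]

    def test_round_trip_random(self, rng, tmp_path):
        ivs = sort_intervals(
            set(random_intervals(rng, 100, ["chr1", "chr2"], 50_000))
        )
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        back = read_bed(p)
        assert back == list(ivs)

    def test_bed6_fields_preserved(self, tmp_path):
        x = iv("chr1", 5, 50, strand="-", name="peak1", score=3.5)
        p = tmp_path / "b6.bed"
        write_bed([x], p)
        [y] = read_bed(p)
        assert (y.name, y.score, y.strand) == ("peak1", 3.5, "-")

    @pytest.mark.parametrize(
        "text,match",
        [
            ("chr1\t100\t100\n", "line 1"),  # empty interval
            ("chr1\t0\n", "fewer than 3"),
            ("chr1\tx\t100\n", "non-integer"),
        ],
    )
    def test_malformed_lines_report_line_number(self, tmp_path, text, match):
        p = tmp_path / "bad.bed"
        p.write_text(text)
        with pytest.raises(ValueError, match=match):
            read_bed(p)

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("track name=x\n# comment\nbrowser position\nchr1\t1\t2\n")
        assert read_bed(p) == [iv("chr1", 1, 2)]


class TestGeneModels:
    def test_minimal_tsv_row(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("g1\tchr1\t+\t1000\t1000,2000\t1500,2500\n")
        [m] = read_gene_models(p)
        assert m.tss == 1000 and len(m.exons) == 2
        assert m.gene_span == iv("chr1", 1000, 2500)

    def test_minus_strand_tss_convention(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("g1\tchr1\t-\t2499\t1000,2000\t1500,2500\n")
        [m] = read_gene_models(p)
        assert m.tss == 2499

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("g1\tchr1\t+\t0\t0\t100\ng1\tchr1\t+\t500\t500\t600\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_models(p)

    def test_inconsistent_tss_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("g1\tchr1\t+\t999\t1000,2000\t1500,2500\n")
        with pytest.raises(ValueError, match="TSS"):
            read_gene_models(p)

    def test_gtf_equals_tsv_model(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        # 1-based closed: gene 1001-2500 == 0-based [1000,2500)
        gtf.write_text(
            'chr1\tsrc\tgene\t1001\t2500\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t1001\t1500\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t2001\t2500\t.\t+\t.\tgene_id "g1";\n'
        )
        tsv = tmp_path / "g.tsv"
        tsv.write_text("g1\tchr1\t+\t1000\t1000,2000\t1500,2500\n")
        [from_gtf] = read_gene_models(gtf)
        [from_tsv] = read_gene_models(tsv)
        assert from_gtf == from_tsv

    def test_gtf_exon_outside_span_rejected(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t1001\t2500\t.\t+\t.\tgene_id "g1";\n'
        )
        with pytest.raises(ValueError, match="outside gene span"):
            read_gene_models(gtf)

    def test_write_read_round_trip(self, tmp_path, default_study):
        p = tmp_path / "rt.tsv"
        write_gene_models(default_study.genes, p)
        back = read_gene_models(p)
        assert sorted(back, key=lambda m: m.gene_id) == sorted(
            default_study.genes, key=lambda m: m.gene_id
        )


def test_chrom_sizes_round_trip(tmp_path):
    p = tmp_path / "sizes.tsv"
    write_chrom_sizes({"chr2": 500, "chr1": 1000}, p)
    back = read_chrom_sizes(p)
    assert back == {"chr1": 1000, "chr2": 500}
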