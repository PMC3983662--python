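import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakscape.core import (
    AnnotationRecord,
    AnnotationSet,
    CoverageTrack,
    GenomeModel,
    Interval,
    ParseError,
    Peak,
    ValidationError,
    derive_3prime,
    derive_promoters,
    flank_both,
    collapse_transcripts,
    hit_flags,
    intersect,
    merge_intervals,
    read_gff,
    read_intervals,
    read_peaks,
    read_track,
    total_bases,
    write_gff,
    write_intervals,
    write_peaks,
    write_track,
)
from conftest import brute_hit_flags, random_intervals


class TestGenomeModel:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            GenomeModel({"chrI": 0})
        with pytest.raises(ValidationError):
            GenomeModel({"chrI": 10}, x_chrom="chrX")
        with pytest.raises(ValidationError):
            GenomeModel({"chrI": 10}, excluded_chroms={"chrM"})

    def test_partitions(self, genome):
        assert genome.autosomes == ["chrI", "chrII"]
        assert genome.included_chroms == ["chrI", "chrII", "chrX"]
        assert "chrM" in genome and "chrM" not in genome.included_chroms

    def test_chromsizes_roundtrip(self, genome, tmp_path):
        path = tmp_path / "sizes"
        genome.write_chromsizes(path)
        again = GenomeModel.from_chromsizes(path, x_chrom="chrX", excluded_chroms=["chrM"])
        assert again.chrom_lengths == genome.chrom_lengths


class TestIntervalTypes:
    def test_interval_validation(self):
        with pytest.raises(ValidationError):
            Interval("chrI", 5, 5)
        with pytest.raises(ValidationError):
            Interval("chrI", -1, 5)

    def test_peak_summit_inside(self):
        with pytest.raises(ValidationError):
            Peak("chrI", 10, 20, summit=20)
        p = Peak("chrI", 10, 20, summit=10)
        assert len(p) == 10

    def test_ncrna_cutoff_enforced(self):
        with pytest.raises(ValidationError):
            AnnotationSet([AnnotationRecord("chrI", 0, 500, "+", "ncRNA_short", "x")])
        with pytest.raises(ValidationError):
            AnnotationSet([AnnotationRecord("chrI", 0, 100, "+", "ncRNA_long", "x")])

    def test_tss_tes_by_strand(self):
        plus = AnnotationRecord("chrI", 100, 200, "+", "gene", "a")
        minus = AnnotationRecord("chrI", 100, 200, "-", "gene", "b")
        assert plus.tss == 100 and plus.tes == 199
        assert minus.tss == 199 and minus.tes == 100


class TestBedGffIO:
    def test_bed_is_native(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrI\t100\t200\n")
        (iv,) = read_intervals(p)
        assert (iv.chrom, iv.start, iv.end) == ("chrI", 100, 200)

    def test_gff_coordinate_shift(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\nchrI\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        (r,) = read_gff(p).records
        assert (r.start, r.end) == (100, 200)

    def test_bed_roundtrip(self, tmp_path, rng, genome):
        ivs = random_intervals(rng, genome, 3)
        path = tmp_path / "x.bed"
        write_intervals(ivs, path)
        assert read_intervals(path) == sorted(ivs, key=lambda i: (i.chrom, i.start, i.end))

    def test_gff_roundtrip_preserves_bases(self, tmp_path):
        recs = [
            AnnotationRecord("chrI", 100, 1500, "+", "gene", "g1"),
            AnnotationRecord("chrI", 2000, 2080, "-", "tRNA", "t1"),
            AnnotationRecord("chrII", 10, 150, "+", "ncRNA_short", "n1"),
        ]
        path = tmp_path / "x.gff3"
        write_gff(AnnotationSet(recs), path)
        again = read_gff(path)
        assert [(r.chrom, r.start, r.end, r.strand, r.cls) for r in again] == [
            (r.chrom, r.start, r.end, r.strand, r.cls) for r in recs
        ]

    def test_unknown_chromosome_rejected(self, tmp_path, genome):
        p = tmp_path / "a.bed"
        p.write_text("chrZZ\t0\t10\n")
        with pytest.raises(ValidationError):
            read_intervals(p, genome=genome)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrI\t1\t100\nchrI\toops\t3\n")
        with pytest.raises(ParseError, match=":2"):
            read_intervals(p)

    def test_peak_roundtrip(self, tmp_path):
        from peakscape.core import PeakSet

        ps = PeakSet([Peak("chrI", 10, 110, 60, 4.5, "p1"), Peak("chrI", 500, 700, 510, 9.0)])
        path = tmp_path / "p.bed"
        write_peaks(ps, path)
        again = read_peaks(path)
        assert [(p.chrom, p.start, p.end, p.summit, p.summit_score) for p in again] == [
            (p.chrom, p.start, p.end, p.summit, p.summit_score) for p in ps
        ]


class TestTrackIO:
    def test_fixedstep_fill_rule(self, tmp_path):
        g = GenomeModel({"chrI": 5})
        p = tmp_path / "w.wig"
        p.write_text("fixedStep chrom=chrI start=1 step=1\n1\n2\n3\n")
        t = read_track(p, g, "wiggle")
        assert t.data["chrI"].tolist() == [1, 2, 3, 0, 0]

    def test_variablestep(self, tmp_path):
        g = GenomeModel({"chrI": 5})
        p = tmp_path / "w.wig"
        p.write_text("variableStep chrom=chrI span=2\n2 7.5\n")
        t = read_track(p, g, "wiggle")
        assert t.data["chrI"].tolist() == [0, 7.5, 7.5, 0, 0]

    def test_bedgraph_fill(self, tmp_path):
        g = GenomeModel({"chrI": 5})
        p = tmp_path / "t.bedgraph"
        p.write_text("chrI\t0\t5\t2.0\n")
        t = read_track(p, g)
        assert np.array_equal(t.data["chrI"], np.full(5, 2.0))

    def test_position_beyond_end(self, tmp_path):
        g = GenomeModel({"chrI": 5})
        p = tmp_path / "t.bedgraph"
        p.write_text("chrI\t0\t9\t1.0\n")
        with pytest.raises(ValidationError):
            read_track(p, g)

    @pytest.mark.parametrize("fmt", ["bedgraph", "wiggle"])
    def test_roundtrip_identity_random_track(self, tmp_path, rng, fmt):
        g = GenomeModel({"chrI": 1000})
        t = CoverageTrack({"chrI": rng.normal(size=1000)}, g)
        path = tmp_path / "t.txt"
        write_track(t, path, fmt)
        again = read_track(path, g, fmt)
        assert np.array_equal(t.data["chrI"], again.data["chrI"])


class TestIntersect:
    def test_one_bp_shared(self):
        _, flags = intersect([Interval("c", 10, 20)], [Interval("c", 19, 30)])
        assert flags[0]

    def test_half_open_adjacency(self):
        _, flags = intersect([Interval("c", 10, 20)], [Interval("c", 20, 30)])
        assert not flags[0]

    def test_min_overlap_argument(self):
        with pytest.raises(ValueError):
            intersect([], [], min_overlap=0)

    def test_against_perbase_oracle(self, rng):
        g = GenomeModel({"chrI": 10_000})
        a = random_intervals(rng, g, 50, 10, 300)
        b = random_intervals(rng, g, 50, 10, 300)
        _, flags = intersect(a, b)
        assert np.array_equal(flags, brute_hit_flags(a, b))
        assert np.array_equal(hit_flags(a, b), brute_hit_flags(a, b))

    def test_min_overlap_oracle(self, rng):
        g = GenomeModel({"chrI": 5_000})
        a = random_intervals(rng, g, 30, 10, 200)
        b = random_intervals(rng, g, 30, 10, 200)
        for k in (5, 50):
            _, flags = intersect(a, b, min_overlap=k)
            assert np.array_equal(flags, brute_hit_flags(a, b, min_overlap=k))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        g = GenomeModel({"chrI": 2_000})
        a = random_intervals(rng, g, 10, 5, 100)
        b = random_intervals(rng, g, 10, 5, 100)
        a_hits_b = hit_flags(a, b).any()
        b_hits_a = hit_flags(b, a).any()
        assert a_hits_b == b_hits_a


class TestMerge:
    def test_book_ended_merge(self):
        merged = merge_intervals([Interval("c", 0, 10), Interval("c", 10, 20)])
        assert merged == [Interval("c", 0, 20)]

    def test_total_bases_counts_union(self):
        assert total_bases([Interval("c", 0, 10), Interval("c", 5, 15)]) == 15

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_merge_preserves_covered_bases(self, seed):
        rng = np.random.default_rng(seed)
        g = GenomeModel({"chrI": 3_000})
        ivs = random_intervals(rng, g, 20, 5, 200)
        cover = np.zeros(3_000, dtype=bool)
        for iv in ivs:
            cover[iv.start : iv.end] = True
        merged = merge_intervals(ivs)
        mcover = np.zeros(3_000, dtype=bool)
        for iv in merged:
            mcover[iv.start : iv.end] = True
        assert np.array_equal(cover, mcover)


class TestPromoters:
    def test_plus_strand(self, genome):
        recs = [AnnotationRecord("chrI", 5000, 8000, "+", "gene", "g")]
        (prom,) = derive_promoters(recs, 1000, genome)
        assert (prom.start, prom.end) == (4000, 5000)

    def test_minus_strand_mirror(self, genome):
        recs = [AnnotationRecord("chrI", 5000, 8000, "-", "gene", "g")]
        (prom,) = derive_promoters(recs, 1000, genome)
        assert (prom.start, prom.end) == (8000, 9000)

    def test_boundary_clamp(self, genome):
        recs = [AnnotationRecord("chrI", 300, 2000, "+", "gene", "g")]
        (prom,) = derive_promoters(recs, 1000, genome)
        assert (prom.start, prom.end) == (0, 300)

    def test_three_prime(self, genome):
        recs = [AnnotationRecord("chrI", 5000, 8000, "+", "gene", "g")]
        (reg,) = derive_3prime(recs, 1000, genome)
        assert (reg.start, reg.end) == (8000, 9000)
        recs = [AnnotationRecord("chrI", 5000, 8000, "-", "gene", "g")]
        (reg,) = derive_3prime(recs, 1000, genome)
        assert (reg.start, reg.end) == (4000, 5000)

    def test_promoter_never_overlaps_gene_body(self, rng, genome):
        recs = [
            AnnotationRecord(
                "chrI", int(s), int(s) + 500, "+" if rng.random() < 0.5 else "-", "gene", f"g{i}"
            )
            for i, s in enumerate(rng.integers(1000, 9000, 20))
        ]
        proms = derive_promoters(recs, 400, genome)
        by_name = {p.name: p for p in proms}
        for r in recs:
            assert by_name[r.name].overlap(r.interval) == 0

    def test_flank_both_covers_tss_and_tes(self, genome):
        recs = [AnnotationRecord("chrI", 5000, 5100, "+", "ncRNA_short", "n")]
        regions = flank_both(recs, 1000, genome)
        cover = np.zeros(10_000, dtype=bool)
        for iv in regions:
            cover[iv.start : iv.end] = True
        assert cover[5000] and cover[5099] and cover[4001] and cover[6098]

    def test_collapse_transcripts(self):
        recs = [
            AnnotationRecord("chrI", 100, 500, "+", "gene", "g1"),
            AnnotationRecord("chrI", 300, 900, "+", "gene", "g1"),
        ]
        (g,) = collapse_transcripts(recs)
        assert (g.start, g.end) == (100, 900)
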