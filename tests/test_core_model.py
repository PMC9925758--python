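import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnasv.core_model import (
    ChromSizes,
    FormatError,
    GenomicInterval,
    SVRecord,
    SmallRNASpecies,
    read_chrom_sizes,
    read_collapsed_reads,
    read_intervals,
    read_score_track,
    read_sv_calls,
    write_chrom_sizes,
    write_collapsed_reads,
    write_intervals,
    write_score_track,
    write_sv_calls,
)
from pirnasv.core_model import ScoreTrack


class TestChromSizes:
    def test_basic(self):
        cs = ChromSizes({"chr1": 100, "chr2": 50})
        assert cs["chr1"] == 100
        assert "chr2" in cs
        assert cs.total() == 150

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            ChromSizes({"chr1": 0})

    def test_roundtrip(self, tmp_path):
        cs = ChromSizes({"chr2": 50, "chr1": 100})
        path = tmp_path / "g.chrom.sizes"
        write_chrom_sizes(cs, path)
        assert read_chrom_sizes(path) == cs


class TestGenomicInterval:
    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)

    def test_negative_start_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)

    def test_bounds_validation(self):
        sizes = ChromSizes({"chr1": 1000})
        GenomicInterval("chr1", 0, 1000).validate(sizes)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 1001).validate(sizes)
        with pytest.raises(ValueError):
            GenomicInterval("chrX", 0, 10).validate(sizes)

    def test_overlaps_half_open(self):
        a = GenomicInterval("chr1", 0, 100)
        assert not a.overlaps(GenomicInterval("chr1", 100, 200))
        assert a.overlaps(GenomicInterval("chr1", 99, 200))
        assert not a.overlaps(GenomicInterval("chr2", 0, 100))


class TestBed:
    def test_bed3_unstranded(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        ivs = read_intervals(p)
        assert ivs == [GenomicInterval("chr1", 0, 100)]
        assert ivs[0].strand == "."

    def test_zero_length_is_error_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t100\t100\n")
        with pytest.raises(FormatError, match="2"):
            read_intervals(p)

    def test_out_of_bounds_is_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t2000\n")
        with pytest.raises(FormatError):
            read_intervals(p, ChromSizes({"chr1": 1000}))

    def test_strand_honored(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tx\t0\t-\n")
        assert read_intervals(p)[0].strand == "-"

    @given(st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2"]),
                  st.integers(0, 5000), st.integers(1, 500),
                  st.sampled_from(["+", "-", "."])),
        min_size=0, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_property(self, tmp_path_factory, raw):
        ivs = sorted(GenomicInterval(c, s, s + l, strand)
                     for c, s, l, strand in raw)
        path = tmp_path_factory.mktemp("bed") / "rt.bed"
        write_intervals(ivs, path)
        assert read_intervals(path) == ivs


class TestSVRecord:
    def test_ins_anchor_and_seq_length(self):
        iv = GenomicInterval("chr1", 1000, 1001)
        rec = SVRecord(iv, "INS", 300, 12, 20.0, "A", "A" * 300)
        assert rec.midpoint == 1000
        with pytest.raises(ValueError):
            SVRecord(iv, "INS", 300, 12, 20.0, "A", "A" * 299)

    def test_spanning_length_must_match(self):
        iv = GenomicInterval("chr1", 0, 300)
        SVRecord(iv, "DEL", 300, 12, 20.0)
        with pytest.raises(ValueError):
            SVRecord(iv, "DEL", 299, 12, 20.0)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            SVRecord(GenomicInterval("chr1", 0, 49), "DEL", 49, 12, 20.0)


class TestSVReaders:
    def test_tsv_ins(self, tmp_path, sizes):
        p = tmp_path / "sv.tsv"
        p.write_text("chr1\t1000\t1000\tINS\t300\t12\t20\tA\t" + "A" * 300 + "\n")
        recs, n_rej = read_sv_calls(p, sizes)
        assert n_rej == 0
        (rec,) = recs
        assert rec.sv_type == "INS" and rec.length == 300
        assert rec.inserted_seq == "A" * 300

    def test_short_sv_rejected_with_count(self, tmp_path, sizes):
        p = tmp_path / "sv.tsv"
        p.write_text("chr1\t1000\t1049\tDEL\t49\t12\t20\tA\n"
                     "chr1\t2000\t2100\tDEL\t100\t12\t20\tA\n")
        with pytest.warns(UserWarning):
            recs, n_rej = read_sv_calls(p, sizes)
        assert n_rej == 1 and len(recs) == 1

    def test_unknown_type_is_error(self, tmp_path, sizes):
        p = tmp_path / "sv.tsv"
        p.write_text("chr1\t1000\t1100\tBND\t100\t12\t20\tA\n")
        with pytest.raises(FormatError):
            read_sv_calls(p, sizes)

    def test_roundtrip(self, tmp_path, sizes):
        recs = [
            SVRecord(GenomicInterval("chr1", 100, 400), "DEL", 300, 15, 30.0, "A"),
            SVRecord(GenomicInterval("chr2", 50, 51), "INS", 120, 11, 25.0, "A",
                     "C" * 120),
            SVRecord(GenomicInterval("chr1", 5000, 5600), "INV", 600, 20, 40.0, "B"),
        ]
        p = tmp_path / "sv.tsv"
        write_sv_calls(recs, p)
        back, n_rej = read_sv_calls(p, sizes)
        assert n_rej == 0
        assert sorted(back, key=lambda r: (r.interval.chrom, r.interval.start)) == \
            sorted(recs, key=lambda r: (r.interval.chrom, r.interval.start))

    def test_vcf_pos_is_one_based(self, tmp_path, sizes):
        p = tmp_path / "sv.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t1001\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL;SVLEN=-300;END=1300;RE=14\n")
        recs, _ = read_sv_calls(p, sizes)
        (rec,) = recs
        assert rec.interval.start == 1000  # converted to 0-based
        assert rec.interval.end == 1300
        assert rec.support_reads == 14

    def test_vcf_ins_with_seq(self, tmp_path, sizes):
        p = tmp_path / "sv.vcf"
        p.write_text("chr1\t501\t.\tN\t<INS>\t.\t.\t"
                     "SVTYPE=INS;SEQ=" + "ACGT" * 25 + ";RE=12\n")
        (rec,), _ = read_sv_calls(p, sizes)
        assert rec.sv_type == "INS" and rec.length == 100
        assert rec.interval.start == 500 and rec.interval.length == 1


class TestCollapsedReads:
    def test_header_count_parsing(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">s1_count5\n" + "TGAAAC" * 5 + "\n")  # 30 nt
        (sp,) = read_collapsed_reads(p)
        assert sp.length == 30 and sp.count == 5

    def test_duplicate_sequences_merged(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">a_count2\nACGTACGTACGTACGTACGTACGTAC\n"
                     ">b_count3\nACGTACGTACGTACGTACGTACGTAC\n")
        (sp,) = read_collapsed_reads(p)
        assert sp.count == 5

    def test_bad_header_is_error(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">species_one\nACGT\n")
        with pytest.raises(FormatError):
            read_collapsed_reads(p)

    def test_mappings_attached(self, tmp_path):
        fa = tmp_path / "r.fa"
        fa.write_text(">s1_count4\nACGTACGTACGTACGTACGTACGTAC\n")
        mp = tmp_path / "m.tsv"
        mp.write_text("s1\tchr1\t100\t+\ns1\tchr2\t500\t-\n")
        (sp,) = read_collapsed_reads(fa, mp)
        assert sp.n_genome_mappings == 2
        assert not sp.is_unique

    def test_roundtrip(self, tmp_path):
        species = [
            SmallRNASpecies("ACGTACGTACGTACGTACGTACGTAC", 4.0,
                            [("chr1", 100, "+"), ("chr2", 500, "-")]),
            SmallRNASpecies("TTTTACGTACGTACGTACGTACGTACGT", 2.5,
                            [("chr1", 900, "+")]),
        ]
        fa, mp = tmp_path / "r.fa", tmp_path / "m.tsv"
        write_collapsed_reads(species, fa, mp)
        back = read_collapsed_reads(fa, mp)
        key = lambda s: s.sequence
        back = sorted(back, key=key)
        orig = sorted(species, key=key)
        assert [s.sequence for s in back] == [s.sequence for s in orig]
        assert [s.count for s in back] == [s.count for s in orig]
        assert [sorted(s.mappings) for s in back] == \
            [sorted(s.mappings) for s in orig]


class TestScoreTrack:
    def test_fill_and_mean(self):
        t = ScoreTrack(fill=0.0)
        t.set_range("chr1", 10, 20, 1.0)
        iv = GenomicInterval("chr1", 10, 30)
        assert t.mean_over(iv) == pytest.approx(0.5)

    def test_roundtrip(self, tmp_path):
        t = ScoreTrack()
        t.set_range("chr1", 0, 5, 0.25)
        t.set_range("chr1", 10, 12, 1.5)
        p = tmp_path / "t.bedGraph"
        write_score_track(t, p)
        back = read_score_track(p)
        assert back.positions("chr1") == t.positions("chr1")
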