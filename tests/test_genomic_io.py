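import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canosa.genomic_io import (
    FormatError,
    GenomeBuild,
    GenomicInterval,
    SampleSupport,
    Segment,
    SiteReadcount,
    VariantRecord,
    normalize_chrom,
    read_readcounts,
    read_segments_bed,
    read_variants_vcf,
    subtract_intervals,
    write_readcounts,
    write_segments_bed,
    write_variants_vcf,
)


class TestReadcounts:
    def test_parses_bam_readcount_style_line(self, tmp_path):
        path = tmp_path / "rc.tsv"
        path.write_text("chr5\t100\tA\t50\tA:25\tG:25\n")
        records = read_readcounts(path)
        assert len(records) == 1
        rec = records[0]
        assert (rec.chrom, rec.pos, rec.ref, rec.depth) == ("chr5", 100, "A", 50)
        assert rec.allele_counts == {"A": 25, "G": 25}
        assert rec.vaf("G") == 0.5

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "rc.tsv"
        path.write_text("")
        assert read_readcounts(path) == []

    def test_counts_exceeding_depth_raise_with_line_number(self, tmp_path):
        path = tmp_path / "rc.tsv"
        path.write_text("1\t10\tA\t50\tA:30\tG:30\n")
        with pytest.raises(FormatError, match=":1:"):
            read_readcounts(path)

    def test_missing_column_raises_format_error(self, tmp_path):
        path = tmp_path / "rc.tsv"
        path.write_text("1\t10\tA\n")
        with pytest.raises(FormatError, match="columns"):
            read_readcounts(path)

    def test_round_trip_preserves_fields(self, tmp_path):
        records = [
            SiteReadcount("1", 5, "C", 40, {"C": 18, "T": 22}),
            SiteReadcount("X", 99, "G", 0, {}),
        ]
        path = tmp_path / "rc.tsv"
        write_readcounts(records, path)
        assert read_readcounts(path) == records


class TestVcf:
    def _write_raw(self, tmp_path, body):
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000000>\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            "normal.WGS\tprimary.WGS\n"
        )
        path = tmp_path / "in.vcf"
        path.write_text(header + body)
        return path

    def test_biallelic_support_vafs(self, tmp_path):
        path = self._write_raw(
            tmp_path, "1\t100\t.\tA\tG\t.\t.\t.\tAD:DP\t50,0:50\t20,20:40\n"
        )
        (rec,) = read_variants_vcf(path)
        assert rec.vaf("normal", "WGS") == 0.0
        assert rec.vaf("primary", "WGS") == 0.5

    def test_multiallelic_site_splits_per_alt(self, tmp_path):
        path = self._write_raw(
            tmp_path, "1\t100\t.\tA\tG,T\t.\t.\t.\tAD:DP\t40,0,0:40\t20,10,5:35\n"
        )
        records = read_variants_vcf(path)
        assert [(r.pos, r.alt) for r in records] == [(100, "G"), (100, "T")]
        assert records[0].support[("primary", "WGS")].var_reads == 10
        assert records[1].support[("primary", "WGS")].var_reads == 5

    def test_unparseable_sample_name_raises(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000>\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tweird\n"
        )
        path = tmp_path / "bad.vcf"
        path.write_text(header + "1\t5\t.\tA\tG\t.\t.\t.\tAD\t3,2\n")
        with pytest.raises(FormatError, match="weird"):
            read_variants_vcf(path)

    def test_round_trip_preserves_key_and_support(self, tmp_path):
        variants = [
            VariantRecord(
                chrom="1",
                pos=1234,
                ref="C",
                alt="T",
                gene="TP53",
                consequence="splice_site, synonymous_coding",
                support={
                    ("normal", "WGS"): SampleSupport(0, 55),
                    ("primary", "WGS"): SampleSupport(30, 60),
                    ("primary", "RNA"): SampleSupport(9, 100),
                },
            ),
            VariantRecord(
                chrom="2",
                pos=77,
                ref="G",
                alt="A",
                consequence="stop_gained",
                support={("primary", "WGS"): SampleSupport(12, 40)},
            ),
        ]
        path = tmp_path / "rt.vcf"
        write_variants_vcf(variants, path)
        back = sorted(read_variants_vcf(path), key=lambda v: v.key)
        original = sorted(variants, key=lambda v: v.key)
        for a, b in zip(original, back):
            assert a.key == b.key
            assert a.gene == b.gene
            assert a.consequence == b.consequence
            assert a.support == b.support


class TestSegmentsBed:
    def test_bed_line_format(self, tmp_path):
        seg = Segment(GenomicInterval("chr1", 0, 1000), 2.0, 1, "CN")
        path = tmp_path / "seg.bed"
        write_segments_bed([seg], path)
        assert path.read_text() == "chr1\t0\t1000\t.\t2\t1\n"

    def test_output_is_sorted(self, tmp_path):
        segs = [
            Segment(GenomicInterval("2", 0, 10), 2.0, 1, "CN"),
            Segment(GenomicInterval("1", 50, 60), 2.0, 1, "CN"),
            Segment(GenomicInterval("1", 0, 10), 2.0, 1, "CN"),
        ]
        path = tmp_path / "seg.bed"
        write_segments_bed(segs, path)
        chroms_starts = [
            (line.split("\t")[0], int(line.split("\t")[1]))
            for line in path.read_text().splitlines()
        ]
        assert chroms_starts == [("1", 0), ("1", 50), ("2", 0)]

    def test_overlapping_same_kind_segments_raise(self, tmp_path):
        segs = [
            Segment(GenomicInterval("1", 0, 100), 2.0, 1, "CN"),
            Segment(GenomicInterval("1", 0, 100), 3.0, 1, "CN"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            write_segments_bed(segs, tmp_path / "seg.bed")

    def test_round_trip(self, tmp_path):
        segs = [
            Segment(GenomicInterval("1", 0, 100), 0.4, 12, "LOH", label="deletion-LOH"),
            Segment(GenomicInterval("2", 5, 50), 0.25, 3, "LOH"),
        ]
        path = tmp_path / "seg.bed"
        write_segments_bed(segs, path)
        back = read_segments_bed(path, "LOH")
        assert [s.interval for s in back] == [s.interval for s in segs]
        assert [s.value for s in back] == [0.4, 0.25]
        assert [s.label for s in back] == ["deletion-LOH", None]


class TestChromNaming:
    @pytest.mark.parametrize(
        "label,expected,canonical",
        [
            ("chr26", "26", True),
            ("26", "26", True),
            ("X", "X", True),
            ("x", "X", True),
            ("chrX", "X", True),
            ("AAEX03025384.1", "AAEX03025384.1", False),
            ("39", "39", False),
        ],
    )
    def test_normalization(self, label, expected, canonical):
        assert normalize_chrom(label) == (expected, canonical)


class TestInvariantsAndTypes:
    @given(
        start=st.integers(min_value=0, max_value=10**8),
        length=st.integers(min_value=1, max_value=10**6),
    )
    @settings(derandomize=True, max_examples=200)
    def test_coordinate_conversion_is_involution(self, start, length):
        # 0-based half-open <-> 1-based inclusive, applied twice
        end = start + length
        one_based = (start + 1, end)
        back = (one_based[0] - 1, one_based[1])
        assert back == (start, end)

    def test_interval_rejects_degenerate_bounds(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("1", -1, 5)

    def test_genome_build_checks_trinuc_sum(self):
        with pytest.raises(ValueError, match="trinucleotide"):
            GenomeBuild(["1"], {"1": 100}, trinucleotide_freqs={"ACA": 0.5})

    def test_subtract_intervals(self):
        iv = GenomicInterval("1", 0, 100)
        cuts = [GenomicInterval("1", 20, 30), GenomicInterval("1", 90, 200)]
        pieces = subtract_intervals(iv, cuts)
        assert [(p.start, p.end) for p in pieces] == [(0, 20), (30, 90)]
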