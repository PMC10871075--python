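"""Round-trip and dialect tests for every reader/writer pair."""

import io

import numpy as np
import pytest

from wavecnv.signal_io import (
    CNVCall,
    DisorderRegion,
    FormatError,
    MarkerMap,
    SignalSample,
    load_reference_model,
    read_calls_bed,
    read_cnv_calls,
    read_disorder_db,
    read_pfb_table,
    read_signal_table,
    save_reference_model,
    write_calls_bed,
    write_cnv_calls,
    write_disorder_db,
    write_pfb_table,
    write_signal_table,
)

from conftest import random_sample


def _roundtrip(markers, sample):
    buf = io.StringIO()
    write_signal_table(markers, sample, buf)
    buf.seek(0)
    return read_signal_table(buf)


class TestSignalTable:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_identity(self, tiny_markers, seed):
        sample = random_sample(tiny_markers, np.random.default_rng(seed))
        m2, s2 = _roundtrip(tiny_markers, sample)
        assert list(m2.marker_id) == list(tiny_markers.marker_id)
        assert list(m2.chrom) == list(tiny_markers.chrom)
        np.testing.assert_array_equal(m2.position, tiny_markers.position)
        np.testing.assert_array_equal(s2.lrr, sample.lrr)
        np.testing.assert_array_equal(s2.baf, sample.baf)
        assert list(s2.genotype) == list(sample.genotype)
        assert s2.sample_id == sample.sample_id

    def test_unsorted_rows_are_sorted_with_their_values(self):
        text = (
            "Name\tChr\tPosition\tS1.Log R Ratio\tS1.B Allele Freq\n"
            "b\t2\t100\t0.2\t0.5\n"
            "a\t1\t500\t0.1\t0.25\n"
            "c\t1\t100\t-0.3\t0.75\n"
        )
        markers, sample = read_signal_table(io.StringIO(text))
        assert list(markers.marker_id) == ["c", "a", "b"]
        np.testing.assert_allclose(sample.lrr, [-0.3, 0.1, 0.2])
        np.testing.assert_allclose(sample.baf, [0.75, 0.25, 0.5])

    def test_unparseable_values_become_missing(self):
        text = (
            "Name\tChr\tPosition\tS1.Log R Ratio\tS1.B Allele Freq\n"
            "a\t1\t100\t0.1\tNaN\n"
            "b\t1\t200\toops\t0.5\n"
        )
        _, sample = read_signal_table(io.StringIO(text))
        assert np.isnan(sample.baf[0]) and sample.lrr[0] == 0.1
        assert np.isnan(sample.lrr[1]) and sample.baf[1] == 0.5

    def test_missing_column_raises(self):
        text = "Name\tChr\tS1.Log R Ratio\tS1.B Allele Freq\na\t1\t0.1\t0.5\n"
        with pytest.raises(FormatError):
            read_signal_table(io.StringIO(text))

    def test_duplicate_marker_raises(self):
        text = (
            "Name\tChr\tPosition\tS1.Log R Ratio\tS1.B Allele Freq\n"
            "a\t1\t100\t0.1\t0.5\na\t1\t200\t0.2\t0.5\n"
        )
        with pytest.raises(FormatError):
            read_signal_table(io.StringIO(text))

    def test_non_integer_position_raises(self):
        text = "Name\tChr\tPosition\tS1.Log R Ratio\tS1.B Allele Freq\na\t1\t1.5\t0.1\t0.5\n"
        with pytest.raises(FormatError):
            read_signal_table(io.StringIO(text))

    def test_empty_map_writes_header_only(self):
        markers = MarkerMap([], [], [])
        sample = SignalSample("S1", [], [])
        buf = io.StringIO()
        write_signal_table(markers, sample, buf)
        assert buf.getvalue().strip().startswith("Name\tChr\tPosition")
        assert len(buf.getvalue().strip().splitlines()) == 1

    def test_single_row_literals(self):
        markers = MarkerMap(["m"], ["1"], [1])
        sample = SignalSample("S1", [0.0], [0.5])
        buf = io.StringIO()
        write_signal_table(markers, sample, buf)
        assert buf.getvalue().splitlines()[1] == "m\t1\t1\t0.0\t0.5"

    def test_length_mismatch_raises(self, tiny_markers):
        with pytest.raises(ValueError):
            write_signal_table(tiny_markers, SignalSample("S", [0.1], [0.5]), io.StringIO())


class TestMarkerMapInvariants:
    def test_unsorted_map_rejected(self):
        with pytest.raises(ValueError):
            MarkerMap(["a", "b"], ["1", "1"], [200, 100])

    def test_bad_chromosome_rejected(self):
        with pytest.raises(FormatError):
            MarkerMap(["a"], ["25"], [100])

    def test_chr_prefix_stripped(self):
        m = MarkerMap(["a", "b"], ["chr1", "chrX"], [100, 50])
        assert list(m.chrom) == ["1", "X"]
        assert list(m.autosome_mask) == [True, False]


class TestRawcnv:
    JOUBERT = (
        "chr2:110852875-110983320 numsnp=66 length=130,446 state2,cn=1 "
        "NB001 startsnp=rs1 endsnp=rs2 conf=123.4"
    )

    def test_parse_deletion_line(self):
        (call,) = read_cnv_calls(self.JOUBERT)
        assert (call.chrom, call.start, call.end) == ("2", 110852875, 110983320)
        assert call.cn == 1 and call.n_snps == 66 and call.confidence == 123.4
        assert call.sample_id == "NB001"
        assert call.length == 130_446

    def test_sample_id_argument_overrides(self):
        (call,) = read_cnv_calls(self.JOUBERT, sample_id="X9")
        assert call.sample_id == "X9"

    def test_empty_file(self):
        assert read_cnv_calls("") == []

    def test_cn2_rejected(self):
        line = "chr1:100-200 numsnp=5 length=101 state3,cn=2 S1 conf=10"
        with pytest.raises(FormatError):
            read_cnv_calls(line)

    def test_missing_conf_defaults_to_zero(self):
        line = "chr1:100-200 numsnp=5 length=101 state2,cn=1 S1 startsnp=a endsnp=b"
        (call,) = read_cnv_calls(line)
        assert call.confidence == 0.0

    def test_malformed_region_raises(self):
        with pytest.raises(FormatError):
            read_cnv_calls("chr1:abc-200 numsnp=5 length=1 state2,cn=1 S1")

    def test_write_read_roundtrip(self):
        calls = [
            CNVCall("S1", "2", 110852875, 110983320, 1, 66, 123.4),
            CNVCall("S1", "10", 500, 900, 3, 12, 7.25),
        ]
        buf = io.StringIO()
        write_cnv_calls(calls, buf)
        back = read_cnv_calls(buf.getvalue())
        for a, b in zip(calls, back):
            assert (a.chrom, a.start, a.end, a.cn, a.n_snps) == (
                b.chrom, b.start, b.end, b.cn, b.n_snps)
            assert a.confidence == pytest.approx(b.confidence)


class TestDisorderDB:
    def test_joubert_row(self):
        text = (
            "name\tchrom\tstart\tend\tdirection\n"
            "Joubert syndrome 4\t2\t110852875\t110983320\tdel\n"
        )
        (region,) = read_disorder_db(io.StringIO(text))
        assert region.name == "Joubert syndrome 4"
        assert (region.chrom, region.start, region.end) == ("2", 110852875, 110983320)

    def test_overlapping_regions_both_returned(self):
        text = (
            "name\tchrom\tstart\tend\tdirection\n"
            "A\t1\t100\t500\tdel\nB\t1\t300\t800\tdup\n"
        )
        assert len(read_disorder_db(io.StringIO(text))) == 2

    def test_end_before_start_raises(self):
        text = "name\tchrom\tstart\tend\tdirection\nA\t1\t500\t100\tdel\n"
        with pytest.raises(FormatError):
            read_disorder_db(io.StringIO(text))

    def test_bad_direction_raises(self):
        with pytest.raises(FormatError):
            DisorderRegion("A", "1", 100, 200, "loss")

    def test_roundtrip_with_expected_cn(self):
        regions = [
            DisorderRegion("A", "1", 100, 500, "del", 1),
            DisorderRegion("B", "2", 300, 800, "dup"),
        ]
        buf = io.StringIO()
        write_disorder_db(regions, buf)
        buf.seek(0)
        assert read_disorder_db(buf) == regions


class TestBed:
    def test_coordinate_convention_shift(self):
        call = CNVCall("S1", "2", 110852875, 110983320, 1, 66, 123.4)
        buf = io.StringIO()
        write_calls_bed([call], buf)
        fields = buf.getvalue().split("\t")
        assert fields[1] == "110852874" and fields[2] == "110983320"

    def test_confidence_clipped_to_1000(self):
        buf = io.StringIO()
        write_calls_bed([CNVCall("S", "1", 100, 200, 3, 5, 2000.0)], buf)
        assert buf.getvalue().strip().endswith("1000")

    def test_empty_set_empty_stream(self):
        buf = io.StringIO()
        write_calls_bed([], buf)
        assert buf.getvalue() == ""

    def test_export_import_recovers_intervals(self):
        calls = [CNVCall("S", "1", 1, 1, 1, 1, 5.0), CNVCall("S", "3", 17, 9000, 4, 3, 1.5)]
        buf = io.StringIO()
        write_calls_bed(calls, buf)
        buf.seek(0)
        back = read_calls_bed(buf)
        assert [(c.chrom, c.start, c.end, c.cn) for c in back] == [
            (c.chrom, c.start, c.end, c.cn) for c in calls
        ]


class TestPfbTable:
    def test_roundtrip_aligned_by_marker_id(self, tiny_markers):
        pfb = np.linspace(0.01, 0.99, len(tiny_markers))
        buf = io.StringIO()
        write_pfb_table(tiny_markers, pfb, buf)
        buf.seek(0)
        np.testing.assert_allclose(read_pfb_table(buf, tiny_markers), pfb)


class TestModelArchive:
    def test_roundtrip(self, tmp_path, small_model):
        save_reference_model(small_model, tmp_path / "model.ref")
        back = load_reference_model(tmp_path / "model.ref")
        assert back.k == small_model.k
        assert back.version == small_model.version
        np.testing.assert_array_equal(back.cluster_sizes, small_model.cluster_sizes)
        np.testing.assert_allclose(back.centroids, small_model.centroids)
        np.testing.assert_allclose(back.marker_mean, small_model.marker_mean)
        np.testing.assert_allclose(back.marker_sd, small_model.marker_sd)
        np.testing.assert_array_equal(
            back.bin_scheme.informative_mask, small_model.bin_scheme.informative_mask
        )
        np.testing.assert_allclose(
            back.reference_features, small_model.reference_features
        )
        np.testing.assert_array_equal(
            back.reference_labels, small_model.reference_labels
        )
        np.testing.assert_array_equal(back.markers.position, small_model.markers.position)
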