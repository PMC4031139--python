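"""Parsing, coordinate conventions and round-trip fidelity of the text IO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucbarrier import io as nbio
from nucbarrier.types import (
    Fragment,
    GenomicInterval,
    ParseError,
    SignalTrack,
    Tag,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestReadIntervals:
    def test_bed6_fields_mapped(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr1\t100\t250\tx\t0\t+\n")
        (iv,) = nbio.read_intervals(path, "bed6")
        assert (iv.chrom, iv.start, iv.end, iv.strand, iv.name) == ("chr1", 100, 250, "+", "x")

    def test_empty_file(self, tmp_path):
        assert nbio.read_intervals(_write(tmp_path, "e.bed", ""), "bed3") == []

    @pytest.mark.parametrize(
        "line",
        ["chr1\t300\t200", "chr1\tx\t200", "chr1\t-5\t200", "chr1\t100"],
    )
    def test_malformed_lines_raise_with_line_number(self, tmp_path, line):
        path = _write(tmp_path, "bad.bed", "chr1\t1\t2\n" + line + "\n")
        with pytest.raises(ParseError) as err:
            nbio.read_intervals(path, "bed3")
        assert err.value.line == 2

    def test_comments_and_blanks_skipped(self, tmp_path):
        path = _write(tmp_path, "c.bed", "# hello\n\ntrack name=x\nchr1\t0\t10\n")
        assert len(nbio.read_intervals(path, "bed3")) == 1


class TestReadTags:
    def test_forward_tag_five_prime_is_start(self, tmp_path):
        path = _write(tmp_path, "t.bed", "chr1\t100\t136\tr\t0\t+\n")
        assert nbio.read_tags(path) == [Tag("chr1", 100, "+")]

    def test_reverse_tag_five_prime_is_end_minus_one(self, tmp_path):
        path = _write(tmp_path, "t.bed", "chr1\t100\t136\tr\t0\t-\n")
        assert nbio.read_tags(path) == [Tag("chr1", 135, "-")]

    def test_missing_strand_is_error(self, tmp_path):
        path = _write(tmp_path, "t.bed", "chr1\t100\t136\tr\t0\t.\n")
        with pytest.raises(ParseError):
            nbio.read_tags(path)


class TestReadFragments:
    def test_bed3_kept_unfiltered(self, tmp_path):
        path = _write(tmp_path, "f.bed", "chr1\t100\t300\nchr1\t100\t350\n")
        frags = nbio.read_fragments(path)
        assert [f.length for f in frags] == [200, 250]

    def test_zero_length_is_error(self, tmp_path):
        path = _write(tmp_path, "f.bed", "chr1\t100\t100\n")
        with pytest.raises(ParseError):
            nbio.read_fragments(path)

    def test_bedpe_outer_coordinates(self, tmp_path):
        path = _write(tmp_path, "f.bedpe", "chr1\t100\t136\tchr1\t264\t300\n")
        (f,) = nbio.read_fragments(path, "bedpe")
        assert (f.start, f.end) == (100, 300)


class TestGenes:
    def test_roundtrip(self, tmp_path):
        path = _write(tmp_path, "g.bed", "chr1\t100\t600\tg1\t0\t-\t12.5\n")
        (g,) = nbio.read_genes(path)
        assert g.tss == 599 and g.tes == 100 and g.expression == 12.5
        out = tmp_path / "out.bed"
        nbio.write_genes([g], str(out))
        assert nbio.read_genes(str(out)) == [g]

    def test_negative_fpkm_is_error(self, tmp_path):
        path = _write(tmp_path, "g.bed", "chr1\t100\t600\tg1\t0\t+\t-1\n")
        with pytest.raises(ParseError):
            nbio.read_genes(path)


class TestBedGraph:
    def test_run_length_merge(self, tmp_path):
        track = SignalTrack({"chr1": np.array([0.0, 0.0, 2.0, 2.0])})
        path = tmp_path / "t.bedGraph"
        nbio.write_bedgraph(track, str(path))
        assert path.read_text().splitlines() == ["chr1\t0\t2\t0", "chr1\t2\t4\t2"]

    def test_all_zero_track_single_record(self, tmp_path):
        track = SignalTrack({"chr1": np.zeros(5)})
        path = tmp_path / "z.bedGraph"
        nbio.write_bedgraph(track, str(path))
        assert path.read_text().splitlines() == ["chr1\t0\t5\t0"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(values=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=50))
    def test_roundtrip_reproduces_values(self, tmp_path_factory, values):
        track = SignalTrack({"chr1": np.array(values, dtype=float)})
        path = tmp_path_factory.mktemp("bg") / "t.bedGraph"
        nbio.write_bedgraph(track, str(path))
        back = nbio.read_bedgraph(str(path), sizes={"chr1": len(values)})
        np.testing.assert_array_equal(back["chr1"], track["chr1"])


class TestTagFragmentRoundtrip:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        specs=st.lists(
            st.tuples(st.integers(min_value=50, max_value=10_000), st.booleans()),
            min_size=1,
            max_size=30,
        )
    )
    def test_tag_roundtrip(self, tmp_path_factory, specs):
        tags = [Tag("chr1", pos, "+" if fwd else "-") for pos, fwd in specs]
        path = tmp_path_factory.mktemp("tags") / "t.bed"
        nbio.write_tags(tags, str(path))
        assert nbio.read_tags(str(path)) == tags

    def test_fragment_roundtrip(self, tmp_path):
        frags = [Fragment("chr1", 10, 160), Fragment("chr2", 0, 250)]
        path = tmp_path / "f.bed"
        nbio.write_fragments(frags, str(path))
        assert nbio.read_fragments(str(path)) == frags


class TestChromSizes:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "g.sizes"
        nbio.write_chrom_sizes({"chr1": 1000, "chr2": 500}, str(path))
        assert nbio.read_chrom_sizes(str(path)) == {"chr1": 1000, "chr2": 500}

    def test_nonpositive_length_rejected(self, tmp_path):
        path = _write(tmp_path, "g.sizes", "chr1\t0\n")
        with pytest.raises(ValueError):
            nbio.read_chrom_sizes(path)


class TestTypeInvariants:
    def test_interval_requires_start_before_end(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 300, 200)

    def test_interval_requires_chrom(self):
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_fragment_midpoint_is_floor(self):
        assert Fragment("chr1", 100, 301).midpoint == 200
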