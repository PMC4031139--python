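"""Strand profiles: normalisation, mirror symmetry, anchors, heatmap, periodicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucbarrier.detect import DHS
from nucbarrier.profiles import (
    StrandProfile,
    anchor_set,
    heatmap_matrix,
    oscillation_metrics,
    strand_profile,
)
from nucbarrier.types import GeneModel, GenomicInterval, Tag

SIZES = {"chr1": 100_000}


class TestStrandProfile:
    def test_no_tags_all_zero(self):
        prof = strand_profile([], [("chr1", 5000, ".")], SIZES, total_tags=100)
        assert not prof.forward.any() and not prof.reverse.any()

    def test_single_tag_unit_value(self):
        # one + tag 10 bp right of one anchor, bin 1, one million total tags
        tags = [Tag("chr1", 5010, "+")]
        prof = strand_profile(tags, [("chr1", 5000, ".")], SIZES, bin=1, total_tags=1_000_000)
        idx = np.flatnonzero(prof.forward)
        assert list(prof.offsets[idx]) == [10]
        assert prof.forward[idx[0]] == pytest.approx(1.0)
        assert not prof.reverse.any()

    def test_minus_anchor_mirrors_to_reverse(self):
        tags = [Tag("chr1", 5010, "+")]
        prof = strand_profile(tags, [("chr1", 5000, "-")], SIZES, bin=1, total_tags=1_000_000)
        idx = np.flatnonzero(prof.reverse)
        assert list(prof.offsets[idx]) == [-10]
        assert not prof.forward.any()

    def test_normalization_halves_when_total_doubles(self):
        rng = np.random.default_rng(0)
        tags = [
            Tag("chr1", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(4000, 6000, size=500)
        ]
        p1 = strand_profile(tags, [("chr1", 5000, ".")], SIZES, total_tags=10_000)
        p2 = strand_profile(tags, [("chr1", 5000, ".")], SIZES, total_tags=20_000)
        np.testing.assert_array_equal(p1.forward, 2.0 * p2.forward)
        np.testing.assert_array_equal(p1.reverse, 2.0 * p2.reverse)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_mirror_symmetry_exact(self, seed):
        # flipping every anchor strand reverses offsets and swaps strand roles
        rng = np.random.default_rng(seed)
        tags = [
            Tag("chr1", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(2000, 98_000, size=300)
        ]
        anchors = [("chr1", int(a), "+") for a in rng.integers(3000, 97_000, size=5)]
        flipped = [(c, p, "-") for c, p, _ in anchors]
        p1 = strand_profile(tags, anchors, SIZES, bin=1, total_tags=1000)
        p2 = strand_profile(tags, flipped, SIZES, bin=1, total_tags=1000)
        np.testing.assert_array_equal(p1.forward, p2.reverse[::-1])
        np.testing.assert_array_equal(p1.reverse, p2.forward[::-1])

    def test_edge_anchors_dropped_and_counted(self):
        anchors = [("chr1", 100, "."), ("chr1", 50_000, ".")]
        prof = strand_profile([Tag("chr1", 50_010, "+")], anchors, SIZES, total_tags=10)
        assert prof.n_anchors == 1 and prof.n_dropped_anchors == 1

    def test_all_anchors_dropped_is_error(self):
        with pytest.raises(ValueError):
            strand_profile([], [("chr1", 10, ".")], SIZES, total_tags=10)

    def test_zero_total_tags_is_error(self):
        with pytest.raises(ValueError):
            strand_profile([], [("chr1", 5000, ".")], SIZES, total_tags=0)


class TestAnchorSet:
    def test_dhs_modes(self):
        d = DHS(GenomicInterval("chr1", 100, 250), summit=180)
        assert anchor_set([d], "edge5") == [("chr1", 100, ".")]
        assert anchor_set([d], "summit") == [("chr1", 180, ".")]

    def test_tss_strand_aware(self):
        g = GeneModel(GenomicInterval("chr1", 100, 600, strand="-", name="g"), "g")
        assert anchor_set([g], "tss") == [("chr1", 599, "-")]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            anchor_set([], "center")


class TestHeatmap:
    def make_genes_and_dhss(self):
        genes, dhss = [], []
        for i, dhs_len in enumerate((300, 150, 80)):
            start = 10_000 + i * 5000
            genes.append(
                GeneModel(GenomicInterval("chr1", start, start + 2000, strand="+", name=f"g{i}"), f"g{i}", float(i))
            )
            # proximal DHS: midpoint inside [start-200, start)
            mid = start - 100
            dhss.append(DHS(GenomicInterval("chr1", mid - dhs_len // 2, mid - dhs_len // 2 + dhs_len), summit=mid))
        return genes, dhss

    def test_rows_sorted_by_dhs_length_desc(self):
        genes, dhss = self.make_genes_and_dhss()
        hm = heatmap_matrix([], genes, dhss, SIZES)
        assert hm.gene_ids == ["g0", "g1", "g2"]
        assert list(hm.dhs_lengths) == [300, 150, 80]

    def test_zero_tag_gene_row_retained(self):
        genes, dhss = self.make_genes_and_dhss()
        hm = heatmap_matrix([], genes, dhss, SIZES)
        assert hm.matrix.shape[0] == 3
        assert not hm.matrix.any()

    def test_zero_fpkm_expression_is_minus_two(self):
        genes, dhss = self.make_genes_and_dhss()
        hm = heatmap_matrix([], genes, dhss, SIZES)
        row = hm.gene_ids.index("g0")  # expression 0.0
        assert hm.expression[row] == pytest.approx(np.log10(0.01))

    def test_unpaired_genes_excluded_and_counted(self):
        genes, dhss = self.make_genes_and_dhss()
        lonely = GeneModel(GenomicInterval("chr1", 50_000, 52_000, strand="+", name="gx"), "gx")
        hm = heatmap_matrix([], genes + [lonely], dhss, SIZES)
        assert hm.n_excluded_genes == 1 and "gx" not in hm.gene_ids


def cosine_profile(period=180.0, flank=1000):
    offsets = np.arange(-flank, flank + 1)
    values = 1.0 + np.cos(2 * np.pi * offsets / period)
    return StrandProfile(
        offsets=offsets,
        forward=values / 2,
        reverse=values / 2,
        bin=1,
        flank=flank,
        n_anchors=1,
        total_tags=1,
    )


class TestOscillation:
    def test_cosine_period_recovered(self):
        prof = cosine_profile(180.0)
        for side in ("left", "right"):
            m = oscillation_metrics(prof, side)
            assert m.period is not None and abs(m.period - 180) <= 1

    def test_white_noise_no_period(self):
        rng = np.random.default_rng(5)
        offsets = np.arange(-1000, 1001)
        rejected = 0
        for _ in range(5):
            prof = StrandProfile(
                offsets=offsets,
                forward=rng.poisson(5.0, offsets.size).astype(float),
                reverse=rng.poisson(5.0, offsets.size).astype(float),
                bin=1,
                flank=1000,
                n_anchors=1,
                total_tags=1,
            )
            if oscillation_metrics(prof, "right").period is None:
                rejected += 1
        assert rejected >= 4

    def test_constant_profile_no_period(self):
        offsets = np.arange(-1000, 1001)
        prof = StrandProfile(
            offsets=offsets,
            forward=np.ones(offsets.size),
            reverse=np.ones(offsets.size),
            bin=1,
            flank=1000,
            n_anchors=1,
            total_tags=1,
        )
        assert oscillation_metrics(prof, "left").period is None

    def test_side_validation(self):
        with pytest.raises(ValueError):
            oscillation_metrics(cosine_profile(), "middle")
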