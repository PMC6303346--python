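import numpy as np
import pandas as pd
import pytest

from chromode import (
    ChromatinMode,
    FeatureClass,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    Group,
    annotate_feature,
    build_signal_matrix,
    classify_chromatin_mode,
    classify_cooccupancy,
    composite_profile,
    order_rows,
    restrict_to_tss,
)
from chromode.core import TagLibrary
from chromode.islands import Island


def make_peak(chrom, start, end, summit=None):
    summit = summit if summit is not None else (start + end) // 2
    return Island(GenomicInterval(chrom, start, end), 1.0, 10, 1, 1e-9, 1e-9, summit)


class TestCooccupancyGrouping:
    def test_overlap_and_fraction(self):
        a = [make_peak("chr1", 0, 100)]
        b = [make_peak("chr1", 50, 150)]
        assignments, frac = classify_cooccupancy(a, b)
        assert frac == 1.0
        assert [x.group for x in assignments] == [Group.A_AND_B]

    def test_disjoint_all_solo(self):
        a = [make_peak("chr1", 0, 100)]
        b = [make_peak("chr1", 500, 600)]
        assignments, frac = classify_cooccupancy(a, b)
        assert frac == 0.0
        assert sorted(x.group.value for x in assignments) == ["A_solo", "B_solo"]

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError):
            classify_cooccupancy([], [make_peak("chr1", 0, 10)])

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(0)

        def peaks(n):
            starts = rng.integers(0, 100_000, n)
            return [make_peak("chr1", int(s), int(s) + int(rng.integers(50, 500)))
                    for s in starts]

        a, b = peaks(500), peaks(500)
        assignments, frac = classify_cooccupancy(a, b)
        a_groups = [x.group for x in assignments if x.peak_id.startswith("A_")]
        # brute-force oracle per A peak
        for x, peak in zip(assignments, a):
            hit = any(peak.region.overlap_length(q.region) >= 1 for q in b)
            assert x.group == (Group.A_AND_B if hit else Group.A_SOLO)
        assert a_groups.count(Group.A_AND_B) / len(a) == frac
        # partition property: every A peak in exactly one group
        assert len(a_groups) == len(a)


class TestTssRestriction:
    genes = [GeneModel("g1", "chr1", "+", 50_000, 70_000),
             GeneModel("g2", "chr1", "+", 65_000, 90_000)]

    def make_assignment(self, center):
        from chromode.cooccupancy import PeakGroupAssignment

        return PeakGroupAssignment(
            "A_0", Group.A_SOLO, GenomicInterval("chr1", center - 50, center + 50),
            center)

    def test_boundary_kept_and_dropped(self):
        kept = restrict_to_tss([self.make_assignment(59_999)], self.genes[:1])
        assert len(kept) == 1 and kept[0].gene_ids == ("g1",)
        assert restrict_to_tss([self.make_assignment(60_001)], self.genes[:1]) == []

    def test_many_to_many(self):
        kept = restrict_to_tss([self.make_assignment(58_000)], self.genes)
        assert kept[0].gene_ids == ("g1", "g2")


class TestFeatureAnnotation:
    genes = [GeneModel("plus", "chr1", "+", 10_000, 30_000),
             GeneModel("minus", "chr2", "-", 50_000, 20_000)]

    @pytest.mark.parametrize(
        "chrom,summit,expected",
        [
            ("chr1", 9_500, FeatureClass.PROMOTER),     # 500 bp upstream of TSS
            ("chr1", 15_000, FeatureClass.GENE_BODY),   # inside + strand body
            ("chr1", 80_000, FeatureClass.INTERGENIC),
            ("chr2", 49_500, FeatureClass.PROMOTER),    # within minus-strand TSS +/- 1 kb
            ("chr2", 30_000, FeatureClass.GENE_BODY),   # strand-ward of TSS + 1 kb
        ],
    )
    def test_classes(self, chrom, summit, expected):
        assert annotate_feature(chrom, summit, self.genes) == expected

    def test_promoter_precedence_over_body(self):
        # 500 bp downstream of the + TSS is in both definitions
        assert annotate_feature("chr1", 10_500, self.genes) == FeatureClass.PROMOTER


class TestSignalMatrix:
    def test_rpkm_arithmetic(self):
        lib = TagLibrary({"chr1": np.full(10, 100_000)})
        # pad library to exactly 1e6 tags elsewhere
        filler = np.arange(1_000_000 - 10) + 5_000_000
        lib = TagLibrary({"chr1": np.concatenate([np.full(10, 100_000), filler])})
        mat = build_signal_matrix([("chr1", 100_050)], lib)
        # the central bin holds all 10 tags: RPKM 100 -> log2(101)
        assert mat.to_numpy().max() == pytest.approx(np.log2(101), abs=1e-9)

    def test_empty_bin_zero(self):
        lib = TagLibrary({"chr1": np.arange(100)})
        mat = build_signal_matrix([("chr1", 50_000)], lib)
        assert mat.shape == (1, 100)
        assert (mat.to_numpy() == 0).all()

    def test_duplicate_tags_scale_invariance(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 200_000, 5_000)
        lib1 = TagLibrary({"chr1": pos})
        lib2 = TagLibrary({"chr1": np.concatenate([pos, pos])})
        m1 = build_signal_matrix([("chr1", 100_000)], lib1)
        m2 = build_signal_matrix([("chr1", 100_000)], lib2)
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)

    def test_zero_tag_library_rejected(self):
        with pytest.raises(ValueError):
            build_signal_matrix([("chr1", 100)], TagLibrary())

    def test_composite_profile_is_column_mean(self):
        rng = np.random.default_rng(2)
        lib = TagLibrary({"chr1": rng.integers(0, 300_000, 20_000)})
        centers = [("chr1", int(c)) for c in rng.integers(20_000, 280_000, 7)]
        mat = build_signal_matrix(centers, lib)
        np.testing.assert_allclose(
            composite_profile(centers, lib), mat.to_numpy().mean(axis=0), atol=1e-12
        )


class TestRowOrdering:
    def _mat(self, rows, index):
        return pd.DataFrame(np.array(rows, dtype=float), index=index)

    def test_me3_ascending(self):
        idx = ["r1", "r2", "r3"]
        me3 = self._mat([[0.5], [0.2], [0.9]], idx)
        ac = self._mat([[0.0], [0.0], [0.0]], idx)
        assert order_rows(me3, ac) == ["r2", "r1", "r3"]

    def test_tie_broken_by_ac_descending(self):
        idx = ["r1", "r2", "r3"]
        me3 = self._mat([[0.0], [0.0], [0.0]], idx)
        ac = self._mat([[1.0], [3.0], [2.0]], idx)
        assert order_rows(me3, ac) == ["r2", "r3", "r1"]

    def test_sorted_keys_monotone(self):
        rng = np.random.default_rng(3)
        idx = [f"r{i}" for i in range(50)]
        me3 = self._mat(rng.random((50, 10)), idx)
        ac = self._mat(rng.random((50, 10)), idx)
        order = order_rows(me3, ac)
        means = me3.loc[order].to_numpy().mean(axis=1)
        assert (np.diff(means) >= -1e-12).all()

    def test_row_id_mismatch_rejected(self):
        me3 = self._mat([[0.0]], ["a"])
        ac = self._mat([[0.0]], ["b"])
        with pytest.raises(ValueError):
            order_rows(me3, ac)


class TestChromatinMode:
    def test_modes(self):
        peak = make_peak("chr1", 1_000, 1_300)
        me3 = [make_peak("chr1", 500, 5_000)]
        ac = [make_peak("chr1", 900, 1_100)]
        assert classify_chromatin_mode(peak, me3, []) == ChromatinMode.ME3
        assert classify_chromatin_mode(peak, [], ac) == ChromatinMode.AC
        assert classify_chromatin_mode(peak, me3, ac) == ChromatinMode.DUAL
        assert classify_chromatin_mode(peak, [], []) == ChromatinMode.UNMARKED
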