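import numpy as np
import pytest

from secircuit import (
    CoverageTrack,
    GeneAnnotation,
    GenomicInterval,
    SuperEnhancerCall,
    assign_enhancer,
    collapse_se_union,
    differential_coverage,
    promoter_activity,
)
from secircuit.landscape import ExpressionCall


def promoter_track(coverages, bin_width=50, spacing=10_000):
    """A track where gene i's promoter window (TSS +/- 500) carries uniform
    per-bin signal coverages[i] / 20, so promoter coverage == coverages[i]."""
    n = (len(coverages) + 1) * spacing // bin_width
    arr = np.zeros(n)
    genes = []
    for i, cov in enumerate(coverages):
        tss = spacing * (i + 1)
        arr[(tss - 500) // bin_width : (tss + 500) // bin_width] = cov / 20
        genes.append(GeneAnnotation(f"g{i}", f"g{i}", "chr1", tss, "+"))
    return genes, CoverageTrack({"chr1": arr}, bin_width, "RPM", 1)


class TestPromoterActivity:
    def test_top_two_thirds_of_three_genes(self):
        genes, track = promoter_track([0.0, 5.0, 10.0])
        calls = promoter_activity(genes, track)
        assert [c.is_expressed for c in calls] == [False, True, True]
        assert [c.promoter_coverage for c in calls] == pytest.approx([0, 5, 10])

    def test_all_equal_coverages_all_expressed(self):
        genes, track = promoter_track([3.0] * 6)
        assert all(c.is_expressed for c in promoter_activity(genes, track))

    def test_empty_annotation_rejected(self):
        _, track = promoter_track([1.0])
        with pytest.raises(ValueError):
            promoter_activity([], track)

    def test_matches_sort_and_slice_oracle(self, rng):
        coverages = list(np.round(rng.lognormal(1, 1, size=99), 3))
        genes, track = promoter_track(coverages, spacing=5000)
        calls = promoter_activity(genes, track)
        threshold = sorted(coverages)[len(coverages) // 3]
        for call, cov in zip(calls, coverages):
            assert call.is_expressed == (cov >= threshold - 1e-9)
        # at least ceil(2n/3) genes expressed
        assert sum(c.is_expressed for c in calls) >= int(np.ceil(2 * 99 / 3))


def expressed_calls(ids):
    return [ExpressionCall(g, 1.0, True) for g in ids]


class TestAssignEnhancer:
    def test_single_expressed_gene_on_chromosome(self):
        genes = [GeneAnnotation("a", "a", "chr1", 1000, "+")]
        enhancer = GenomicInterval("chr1", 90_000, 95_000)
        assert assign_enhancer(enhancer, expressed_calls(["a"]), genes) == "a"

    def test_equidistant_tie_goes_to_leftmost_tss(self):
        genes = [
            GeneAnnotation("left", "left", "chr1", 1000, "+"),
            GeneAnnotation("right", "right", "chr1", 3000, "+"),
        ]
        enhancer = GenomicInterval("chr1", 1900, 2100)  # center 2000
        assert assign_enhancer(enhancer, expressed_calls(["left", "right"]), genes) == "left"

    def test_no_expressed_gene_on_chromosome_returns_none(self):
        genes = [GeneAnnotation("a", "a", "chr2", 1000, "+")]
        enhancer = GenomicInterval("chr1", 0, 100)
        assert assign_enhancer(enhancer, expressed_calls(["a"]), genes) is None

    def test_unexpressed_genes_never_assigned(self):
        genes = [
            GeneAnnotation("near", "near", "chr1", 2000, "+"),
            GeneAnnotation("far", "far", "chr1", 50_000, "+"),
        ]
        calls = [ExpressionCall("near", 0.0, False), ExpressionCall("far", 9.0, True)]
        assert assign_enhancer(GenomicInterval("chr1", 1900, 2100), calls, genes) == "far"

    def test_matches_exhaustive_distance_scan(self, rng):
        genes = [
            GeneAnnotation(f"g{i}", f"g{i}", "chr1", int(t), "+")
            for i, t in enumerate(sorted(rng.choice(500_000, 20, replace=False)))
        ]
        expressed = expressed_calls([g.gene_id for g in genes[::2]])
        expressed_set = {e.gene_id for e in expressed}
        for _ in range(100):
            start = int(rng.integers(0, 490_000))
            enhancer = GenomicInterval("chr1", start, start + int(rng.integers(100, 10_000)))
            center = (enhancer.start + enhancer.end) // 2
            best = min(
                (g for g in genes if g.gene_id in expressed_set),
                key=lambda g: (abs(g.tss - center), g.tss),
            )
            assert assign_enhancer(enhancer, expressed, genes) == best.gene_id


def se_set(spans, is_super=True):
    return [
        SuperEnhancerCall(GenomicInterval("chr1", s, e), [], 1.0, i + 1, is_super)
        for i, (s, e) in enumerate(spans)
    ]


class TestCollapseSeUnion:
    def test_identical_sets_idempotent(self):
        spans = [(0, 100), (50, 200), (5000, 6000)]
        union = collapse_se_union([se_set(spans), se_set(spans)])
        assert [(r.start, r.end) for r in union] == [(0, 200), (5000, 6000)]

    def test_disjoint_sets_concatenate_sorted(self):
        union = collapse_se_union([se_set([(5000, 6000)]), se_set([(0, 100)])])
        assert [(r.start, r.end) for r in union] == [(0, 100), (5000, 6000)]

    def test_typical_enhancers_excluded_from_union(self):
        union = collapse_se_union(
            [se_set([(0, 100)]), se_set([(500, 600)], is_super=False)]
        )
        assert [(r.start, r.end) for r in union] == [(0, 100)]

    def test_order_invariant_and_matches_mask_oracle(self, rng):
        sets = [
            se_set(
                [(int(s), int(s) + int(w)) for s, w in
                 zip(rng.integers(0, 50_000, 25), rng.integers(100, 2000, 25))]
            )
            for _ in range(4)
        ]
        union = collapse_se_union(sets)
        reordered = collapse_se_union(sets[::-1])
        assert union == reordered
        mask = np.zeros(60_000, dtype=bool)
        for s in sets:
            for c in s:
                mask[c.region.start : c.region.end] = True
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask, [0]]).astype(int)))
        assert [(r.start, r.end) for r in union] == list(zip(edges[::2], edges[1::2]))


def region_track(values, mapped_reads=1_000_000, bin_width=50):
    return CoverageTrack(
        {"chr1": np.asarray(values, dtype=float)}, bin_width, "RPM", mapped_reads
    )


def one_bin_regions(n, bin_width=50):
    return [GenomicInterval("chr1", i * bin_width, (i + 1) * bin_width) for i in range(n)]


class TestDifferentialCoverage:
    pairs = {"A": ["a"], "B": ["b"]}

    def test_identical_conditions_all_stable_with_zero_lfc(self, rng):
        values = rng.lognormal(3, 1, size=30)
        tracks = {"a": region_track(values), "b": region_track(values)}
        results = differential_coverage(one_bin_regions(30), tracks, self.pairs)
        assert all(r.status == "stable" for r in results)
        assert all(r.log2_fold_change == 0.0 for r in results)

    def test_empty_regions_stable_not_nan(self):
        tracks = {"a": region_track([0.0]), "b": region_track([0.0])}
        (r,) = differential_coverage(one_bin_regions(1), tracks, self.pairs)
        assert r.log2_fold_change == 0.0 and r.status == "stable"

    def test_antisymmetric_under_condition_swap(self, rng):
        tracks = {
            "a": region_track(rng.lognormal(3, 2, size=40)),
            "b": region_track(rng.lognormal(3, 2, size=40)),
        }
        regions = one_bin_regions(40)
        fwd = differential_coverage(regions, tracks, {"A": ["a"], "B": ["b"]})
        rev = differential_coverage(regions, tracks, {"A": ["b"], "B": ["a"]})
        swap = {"gained": "lost", "lost": "gained", "stable": "stable"}
        for f, r in zip(fwd, rev):
            assert r.log2_fold_change == pytest.approx(-f.log2_fold_change, abs=1e-12)
            assert r.status == swap[f.status]

    def test_planted_four_fold_effects_classified_without_false_calls(self, rng):
        # 10 gained, 10 lost at 4x, 200 stable, mild multiplicative noise
        base = rng.lognormal(5, 0.5, size=220)
        a = base.copy()
        b = base.copy()
        b[:10] *= 4.0  # gained
        a[10:20] *= 4.0  # lost
        noise = lambda: rng.normal(1.0, 0.02, size=220)
        tracks = {"a": region_track(a * noise()), "b": region_track(b * noise())}
        results = differential_coverage(one_bin_regions(220), tracks, self.pairs)
        statuses = [r.status for r in results]
        assert statuses[:10] == ["gained"] * 10
        assert statuses[10:20] == ["lost"] * 10
        assert statuses[20:] == ["stable"] * 200

    def test_missing_condition_rejected(self, rng):
        tracks = {"a": region_track([1.0])}
        with pytest.raises(ValueError):
            differential_coverage(one_bin_regions(1), tracks, {"A": ["a"], "B": []})

    def test_raw_track_without_mapped_reads_rejected(self):
        raw = CoverageTrack({"chr1": np.ones(5)}, 50, "raw_counts", 0)
        rpm = region_track(np.ones(5))
        with pytest.raises(ValueError, match="mapped_reads"):
            differential_coverage(
                one_bin_regions(5), {"a": raw, "b": rpm}, self.pairs
            )
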