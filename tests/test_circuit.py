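from itertools import combinations

import numpy as np
import pytest

from secircuit import (
    CoverageTrack,
    GenomicInterval,
    build_occupancy_matrix,
    compare_crcs,
    enrichment_call,
    infer_crc,
)
from secircuit.circuit import CRCGraph, _max_complete_subgraph


def flat_track(value, n_bins=100, bin_width=50):
    return CoverageTrack({"chr1": np.full(n_bins, float(value))}, bin_width, "RPM", 1)


REGION = GenomicInterval("chr1", 0, 1000)


class TestEnrichmentCall:
    def test_zero_target_signal_never_enriched(self):
        assert not enrichment_call(flat_track(0), REGION, flat_track(0))

    def test_ten_fold_over_igg_at_min_fold_three(self):
        assert enrichment_call(flat_track(10), REGION, flat_track(1), min_fold=3)
        assert not enrichment_call(flat_track(2), REGION, flat_track(1), min_fold=3)

    def test_floor_prevents_blowup_on_empty_control(self):
        # target 1.0 vs control 0: without the floor any signal would pass
        assert not enrichment_call(
            flat_track(1.0), REGION, flat_track(0), min_fold=3, floor=0.5
        )
        assert enrichment_call(
            flat_track(2.0), REGION, flat_track(0), min_fold=3, floor=0.5
        )

    def test_planted_bound_regions_called_accurately(self, rng):
        # planted bound/unbound regions at 8x IgG, Poisson noise, 20 seeds
        n, correct, total = 40, 0, 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            bound = r.random(n) < 0.5
            igg = CoverageTrack(
                {"chr1": r.poisson(1.0, n * 20).astype(float)}, 50, "RPM", 1
            )
            arr = r.poisson(np.where(np.repeat(bound, 20), 8.0, 1.0)).astype(float)
            target = CoverageTrack({"chr1": arr}, 50, "RPM", 1)
            for i in range(n):
                region = GenomicInterval("chr1", i * 1000, (i + 1) * 1000)
                call = enrichment_call(target, region, igg, min_fold=3, floor=0.5)
                correct += call == bound[i]
                total += 1
        assert correct / total >= 0.95


class TestOccupancyMatrix:
    def make_tracks(self, rng, n_regions=30):
        # per-region constant signal per target
        def track(values):
            return CoverageTrack(
                {"chr1": np.repeat(values, 20).astype(float)}, 50, "RPM", 1
            )
        values = {
            "H3K27ac": rng.lognormal(1, 1, n_regions),
            "TFX": rng.lognormal(0.5, 1, n_regions),
            "IgG": np.full(n_regions, 0.3),
        }
        tracks = {t: track(v) for t, v in values.items()}
        regions = [
            GenomicInterval("chr1", i * 1000, (i + 1) * 1000) for i in range(n_regions)
        ]
        return tracks, regions, values

    def test_all_zero_tracks_give_empty_matrix(self):
        tracks = {t: flat_track(0) for t in ("H3K27ac", "TFX", "IgG")}
        matrix = build_occupancy_matrix(tracks, [REGION])
        assert matrix.values.shape == (0, 3)

    def test_region_enriched_for_single_target_retained_with_full_row(self):
        tracks = {
            "H3K27ac": flat_track(0.1),
            "MEIS1": flat_track(9.0),
            "IgG": flat_track(0.3),
        }
        matrix = build_occupancy_matrix(tracks, [REGION])
        assert len(matrix.regions) == 1
        row = dict(zip(matrix.targets, matrix.values[0]))
        assert row["MEIS1"] == pytest.approx(9.0)
        assert row["H3K27ac"] == pytest.approx(0.1)

    def test_rows_sorted_by_descending_h3k27ac(self, rng):
        tracks, regions, values = self.make_tracks(rng)
        matrix = build_occupancy_matrix(tracks, regions)
        col = matrix.values[:, matrix.targets.index("H3K27ac")]
        assert np.all(np.diff(col) <= 0)
        # sorting oracle on retained regions
        retained = {(r.start, r.end) for r in matrix.regions}
        expected_order = sorted(
            (i for i in range(len(regions))
             if (regions[i].start, regions[i].end) in retained),
            key=lambda i: -values["H3K27ac"][i],
        )
        got_starts = [r.start for r in matrix.regions]
        assert got_starts == [regions[i].start for i in expected_order]


def oracle_members(nodes, edges):
    """Exhaustive enumeration over all subsets: the largest set complete under
    the directed edges with self-loops, ties to the lexicographically
    smallest sorted tuple."""
    best: tuple = ()
    for k in range(len(nodes), 0, -1):
        candidates = [
            subset
            for subset in combinations(sorted(nodes), k)
            if all((i, j) in edges for i in subset for j in subset)
        ]
        if candidates:
            best = min(candidates)
            break
    return list(best)


class TestMaxCompleteSubgraph:
    def test_agrees_with_exhaustive_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(42)
        for _ in range(250):
            n = int(rng.integers(2, 9))
            nodes = [f"TF{i}" for i in range(n)]
            density = rng.uniform(0.3, 0.9)
            edges = {
                (i, j)
                for i in nodes
                for j in nodes
                if rng.random() < density or i == j and rng.random() < 0.8
            }
            assert _max_complete_subgraph(nodes, edges) == oracle_members(nodes, edges)


def make_graph(condition, members, candidates=("A", "B", "C", "D", "E", "F")):
    edges = {(i, j) for i in members for j in members}
    return CRCGraph(condition, list(candidates), list(members), edges, sorted(members))


class TestInferCrc:
    def setup_tracks(self, edges, tfs, spans):
        """TF i's track carries signal over TF j's SE span iff (i, j) in edges."""
        n_bins = 20 * len(tfs)
        tracks = {}
        for i in tfs:
            arr = np.full(n_bins, 0.1)
            for j in tfs:
                if (i, j) in edges:
                    s, e = spans[j]
                    arr[s // 50 : e // 50] = 10.0
            tracks[i] = CoverageTrack({"chr1": arr}, 50, "RPM", 1)
        igg = CoverageTrack({"chr1": np.full(n_bins, 0.1)}, 50, "RPM", 1)
        return tracks, igg

    def run(self, edges, tfs=("A", "B", "C", "D", "E"), expressed=None):
        spans = {tf: (i * 1000, (i + 1) * 1000) for i, tf in enumerate(tfs)}
        assignments = {
            tf: [GenomicInterval("chr1", s, e)] for tf, (s, e) in spans.items()
        }
        tracks, igg = self.setup_tracks(edges, tfs, spans)
        return infer_crc(
            "cond", list(tfs), assignments, tracks, igg,
            expressed if expressed is not None else set(tfs),
        )

    def test_complete_binding_all_members(self):
        tfs = ("A", "B", "C", "D", "E")
        graph = self.run({(i, j) for i in tfs for j in tfs})
        assert graph.members == list(tfs)
        assert graph.edges == {(i, j) for i in tfs for j in tfs}

    def test_tf_without_self_loop_excluded(self):
        tfs = ("A", "B", "C", "D", "E")
        edges = {(i, j) for i in tfs for j in tfs} - {("E", "E")}
        graph = self.run(edges)
        assert graph.members == ["A", "B", "C", "D"]

    def test_unexpressed_or_unassigned_candidates_inadmissible(self):
        tfs = ("A", "B", "C", "D", "E")
        edges = {(i, j) for i in tfs for j in tfs}
        graph = self.run(edges, expressed={"A", "B", "C"})
        assert graph.admissible == ["A", "B", "C"]
        assert graph.members == ["A", "B", "C"]

    def test_relaxed_mode_keeps_members_bound_by_enough_others(self):
        tfs = ("A", "B", "C", "D", "E")
        # E lacks a self-loop and one inbound edge: excluded under the strict
        # complete-subgraph rule, retained under "bound by >= 3 members"
        edges = {(i, j) for i in tfs for j in tfs} - {("E", "E"), ("A", "E")}
        spans = {tf: (i * 1000, (i + 1) * 1000) for i, tf in enumerate(tfs)}
        assignments = {
            tf: [GenomicInterval("chr1", s, e)] for tf, (s, e) in spans.items()
        }
        tracks, igg = self.setup_tracks(edges, tfs, spans)
        strict = infer_crc("c", list(tfs), assignments, tracks, igg, set(tfs))
        relaxed = infer_crc(
            "c", list(tfs), assignments, tracks, igg, set(tfs), min_inbound=3
        )
        assert strict.members == ["A", "B", "C", "D"]
        assert relaxed.members == ["A", "B", "C", "D", "E"]

    def test_no_admissible_candidates_gives_empty_circuit(self):
        graph = self.run(set(), expressed=set())
        assert graph.members == [] and graph.edges == set()


class TestCompareCrcs:
    def test_identical_graphs_all_shared(self):
        a = make_graph("x", ["A", "B"])
        delta = compare_crcs(a, make_graph("y", ["A", "B"]))
        assert delta == {"shared": ["A", "B"], "lost": [], "gained": []}

    def test_disjoint_members_nothing_shared(self):
        delta = compare_crcs(make_graph("x", ["A", "B"]), make_graph("y", ["E", "F"]))
        assert delta == {"shared": [], "lost": ["A", "B"], "gained": ["E", "F"]}

    def test_planted_shift_recovered_and_symmetric_under_swap(self):
        a = make_graph("x", ["A", "B", "C", "D"])
        b = make_graph("y", ["C", "D", "E", "F"])
        delta = compare_crcs(a, b)
        assert delta == {"shared": ["C", "D"], "lost": ["A", "B"], "gained": ["E", "F"]}
        rev = compare_crcs(b, a)
        assert rev["shared"] == delta["shared"]
        assert rev["lost"] == delta["gained"] and rev["gained"] == delta["lost"]

    def test_different_candidate_universes_rejected(self):
        a = make_graph("x", ["A"], candidates=("A", "B"))
        b = make_graph("y", ["A"], candidates=("A", "C"))
        with pytest.raises(ValueError):
            compare_crcs(a, b)
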