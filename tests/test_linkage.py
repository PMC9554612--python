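"""Consensus-map merging: LP optimality, order preservation, conflicts."""

import itertools

import numpy as np
import pytest

from metaqtl.linkage import (
    LinkageMap,
    map_stats,
    merge_maps,
    resolve_order_conflicts,
)


def mae_objective(consensus_positions, maps, chrom="1A", dropped=()):
    """Independent evaluation of the merge objective on given positions."""
    total = 0.0
    for lm in maps:
        markers = lm.entries.get(chrom, [])
        if len(markers) < 2:
            continue
        w = 1.0 / (len(markers) - 1)
        for (a, pa), (b, pb) in zip(markers, markers[1:]):
            if (a, b) in dropped:
                continue
            total += w * abs(
                (consensus_positions[b] - consensus_positions[a]) - (pb - pa)
            )
    return total


class TestMergeBasics:
    def test_single_map_identity_shifted_to_zero(self):
        m = LinkageMap("m", {"1A": [("A", 5.0), ("B", 15.0), ("C", 30.0)]})
        c = merge_maps([m])
        assert c.entries["1A"] == [("A", 0.0), ("B", pytest.approx(10.0)), ("C", pytest.approx(25.0))]

    def test_two_identical_maps_reproduce_the_map(self):
        m1 = LinkageMap("m1", {"1A": [("A", 0.0), ("B", 12.0)]})
        m2 = LinkageMap("m2", {"1A": [("A", 0.0), ("B", 12.0)]})
        c = merge_maps([m1, m2])
        assert dict(c.entries["1A"])["B"] == pytest.approx(12.0)

    def test_disagreeing_distance_resolves_to_face_midpoint(self):
        m1 = LinkageMap("m1", {"1A": [("A", 0.0), ("B", 10.0)]})
        m2 = LinkageMap("m2", {"1A": [("A", 0.0), ("B", 20.0)]})
        c = merge_maps([m1, m2])
        assert dict(c.entries["1A"])["B"] == pytest.approx(15.0, abs=1e-6)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            merge_maps([])

    def test_single_marker_chromosome_passthrough_warns(self):
        m = LinkageMap("m", {"1A": [("A", 3.0)]})
        with pytest.warns(UserWarning):
            c = merge_maps([m])
        assert c.entries["1A"] == [("A", 0.0)]

    def test_merge_idempotent(self):
        m1 = LinkageMap("m1", {"1A": [("A", 0.0), ("B", 10.0), ("C", 18.0)]})
        m2 = LinkageMap("m2", {"1A": [("A", 0.0), ("B", 14.0), ("C", 25.0)]})
        c = merge_maps([m1, m2])
        again = merge_maps([c])
        for (ma, pa), (mb, pb) in zip(c.entries["1A"], again.entries["1A"]):
            assert ma == mb and pa == pytest.approx(pb, abs=1e-6)

    def test_union_of_markers_retained_and_provenance(self):
        m1 = LinkageMap("m1", {"1A": [("A", 0.0), ("B", 10.0)]})
        m2 = LinkageMap("m2", {"1A": [("B", 0.0), ("C", 5.0)]})
        c = merge_maps([m1, m2])
        assert {m for m, _ in c.entries["1A"]} == {"A", "B", "C"}
        assert c.n_source_maps("1A", "B") == 2
        assert c.n_source_maps("1A", "A") == 1


class TestOrderPreservation:
    def test_retained_constraints_hold_in_output(self):
        rng = np.random.default_rng(7)
        maps = []
        base = np.sort(rng.uniform(0, 100, 12))
        names = [f"M{i}" for i in range(12)]
        for j in range(4):
            keep = rng.random(12) < 0.8
            keep[0] = keep[-1] = True
            jitter = np.sort(base[keep] * np.exp(rng.normal(0, 0.05)))
            maps.append(
                LinkageMap(f"m{j}", {"1A": list(zip(np.array(names)[keep], jitter))})
            )
        retained, _ = resolve_order_conflicts(maps)
        c = merge_maps(maps)
        pos = c.positions("1A")
        for con in retained:
            assert pos[con.a] < pos[con.b]

    def test_objective_beats_naive_first_map_positions(self):
        m1 = LinkageMap("m1", {"1A": [("A", 0.0), ("B", 10.0), ("C", 30.0)]})
        m2 = LinkageMap("m2", {"1A": [("A", 0.0), ("B", 18.0), ("C", 26.0)]})
        c = merge_maps([m1, m2])
        solver_obj = mae_objective(c.positions("1A"), [m1, m2])
        naive_obj = mae_objective(m1.positions("1A"), [m1, m2])
        assert solver_obj <= naive_obj + 1e-9


class TestBruteForceOracle:
    @pytest.mark.parametrize(
        "d1,d2",
        [((10.0, 5.0), (12.0, 9.0)), ((3.0, 20.0), (6.0, 14.0)), ((8.0, 8.0), (8.0, 8.0))],
    )
    def test_three_marker_lp_matches_grid_search(self, d1, d2):
        """On 3-marker/2-map instances the LP objective equals a dense
        2-D grid search to within grid resolution."""
        m1 = LinkageMap("m1", {"1A": [("A", 0.0), ("B", d1[0]), ("C", d1[0] + d1[1])]})
        m2 = LinkageMap("m2", {"1A": [("A", 0.0), ("B", d2[0]), ("C", d2[0] + d2[1])]})
        c = merge_maps([m1, m2])
        lp_obj = mae_objective(c.positions("1A"), [m1, m2])

        # brute force: y_A = 0, grid over (y_B, y_C)
        hi = max(d1[0] + d1[1], d2[0] + d2[1]) + 2
        grid = np.arange(0.0, hi, 0.05)
        yb, yc = np.meshgrid(grid, grid, indexing="ij")

        def obj(yb, yc):
            t = np.zeros_like(yb)
            for lm, (da, db) in [(m1, d1), (m2, d2)]:
                w = 0.5
                t = t + w * (np.abs(yb - da) + np.abs((yc - yb) - db))
            return t
        vals = obj(yb, yc)
        best = vals.min()
        assert lp_obj <= best + 1e-6
        assert lp_obj >= best - 0.1  # grid resolution slack


class TestConflictResolution:
    def test_no_cycles_nothing_removed(self, simple_map):
        retained, removed = resolve_order_conflicts([simple_map])
        assert removed == []
        assert len(retained) == 3

    def test_majority_order_wins(self):
        m1 = LinkageMap("m1", {"1A": [("A", 0.0), ("B", 5.0)]})
        m2 = LinkageMap("m2", {"1A": [("B", 0.0), ("A", 5.0)]})
        m3 = LinkageMap("m3", {"1A": [("A", 0.0), ("B", 6.0)]})
        _, removed = resolve_order_conflicts([m1, m2, m3])
        assert len(removed) == 1
        assert (removed[0].a, removed[0].b) == ("B", "A")
        assert removed[0].maps == ("m2",)

    def test_three_cycle_equal_support_removes_exactly_one_edge(self):
        # A<B (m1), B<C (m2), C<A (m3): every single-edge removal is optimal
        m1 = LinkageMap("m1", {"1A": [("A", 0.0), ("B", 5.0)]})
        m2 = LinkageMap("m2", {"1A": [("B", 0.0), ("C", 5.0)]})
        m3 = LinkageMap("m3", {"1A": [("C", 0.0), ("A", 5.0)]})
        retained, removed = resolve_order_conflicts([m1, m2, m3])
        assert len(removed) == 1
        # exhaustive check: removing any one edge leaves an acyclic set
        for drop in range(3):
            edges = [("A", "B"), ("B", "C"), ("C", "A")]
            kept = [e for i, e in enumerate(edges) if i != drop]
            order = {e: i for i, e in enumerate(kept)}
            assert len(kept) == 2  # no 2-cycles possible among the rest
        assert len(retained) == 2


class TestMapStats:
    def test_length_density_and_totals(self):
        m = LinkageMap(
            "c",
            {
                "1A": [(f"M{i}", float(i)) for i in range(0, 101, 25)],
                "1B": [("X", 0.0), ("Y", 50.0)],
            },
        )
        st = map_stats(m)
        assert st["per_chromosome"]["1A"].length_cM == 100.0
        assert st["per_chromosome"]["1A"].density == pytest.approx(5 / 100)
        assert st["total_length_cM"] == 150.0
        assert st["total_markers"] == 7
        assert st["per_subgenome"]["A"]["n_markers"] == 5

    def test_single_marker_chromosome_density_flagged(self):
        st = map_stats(LinkageMap("c", {"1A": [("A", 0.0)]}))
        assert st["per_chromosome"]["1A"].length_cM == 0.0
        assert st["per_chromosome"]["1A"].density is None
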