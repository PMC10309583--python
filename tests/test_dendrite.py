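"""Branch orders, position scores, tree summaries and the count regression."""

import numpy as np
import pytest

from mitomorph import (
    DendriteTree,
    assign_branch_orders,
    dendrite_summary,
    fit_count_vs_length,
    order_fractions,
    position_score,
    read_tree_json,
    write_tree_json,
)
from mitomorph.dendrite import BranchAssignment


def path_tree(n=5, step=10.0):
    xy = {i: (0.0, i * step) for i in range(n)}
    parent = {0: None, **{i: i - 1 for i in range(1, n)}}
    return DendriteTree(xy=xy, parent=parent)


def bifurcating_tree():
    # primary 0-1, two daughters 1-2 and 1-3
    xy = {0: (0.0, 0.0), 1: (0.0, 10.0), 2: (-5.0, 18.0), 3: (5.0, 18.0)}
    parent = {0: None, 1: 0, 2: 1, 3: 1}
    return DendriteTree(xy=xy, parent=parent)


def full_binary_tree(depth):
    # a primary dendrite (order I) that then bifurcates fully: 2^(k-1)
    # branches of order k
    xy = {0: (0.0, 0.0), 1: (0.0, 8.0)}
    parent = {0: None, 1: 0}
    frontier = [(1, 0.0, 8.0)]
    nid = 1
    for level in range(2, depth + 1):
        nxt = []
        for p, x, y in frontier:
            for dx in (-1, 1):
                nid += 1
                nx, ny = x + dx * 40.0 / 2**level, y + 8.0
                xy[nid] = (nx, ny)
                parent[nid] = p
                nxt.append((nid, nx, ny))
        frontier = nxt
    return DendriteTree(xy=xy, parent=parent)


class TestBranchOrders:
    def test_unbranched_path_is_single_order_one_branch(self):
        tree = assign_branch_orders(path_tree())
        assert len(tree.branches) == 1
        assert tree.branches[0].order == 1
        assert tree.branches[0].length_um == pytest.approx(40.0)

    def test_single_bifurcation_gives_two_order_two_daughters(self):
        tree = assign_branch_orders(bifurcating_tree())
        orders = sorted(b.order for b in tree.branches)
        assert orders == [1, 2, 2]

    def test_full_binary_tree_branch_counts(self):
        # root edge is order I; 2^(k-1) branches of each deeper order
        tree = assign_branch_orders(full_binary_tree(5))
        from collections import Counter

        counts = Counter(b.order for b in tree.branches)
        assert counts == {k: 2 ** (k - 1) for k in range(1, 6)}

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError):
            DendriteTree(xy={0: (0, 0), 1: (1, 1)}, parent={0: 1, 1: 0})

    def test_branch_lengths_partition_total_length(self):
        tree = assign_branch_orders(full_binary_tree(4))
        assert sum(b.length_um for b in tree.branches) == pytest.approx(
            tree.total_length_um()
        )


class TestPositionScore:
    def test_proximal_node_scores_zero(self):
        tree = assign_branch_orders(path_tree())
        a = position_score(tree, (0.0, 0.0))
        assert a.assigned and a.score == pytest.approx(0.0)

    def test_midpoint_scores_half(self):
        tree = assign_branch_orders(path_tree())
        a = position_score(tree, (0.4, 20.0))
        assert a.score == pytest.approx(0.5, abs=0.01)

    def test_far_centroid_flagged_unassigned(self):
        tree = assign_branch_orders(path_tree())
        a = position_score(tree, (30.0, 20.0), snap_um=1.0)
        assert not a.assigned and a.branch_id is None

    def test_invariance_under_rigid_motion(self):
        tree = assign_branch_orders(bifurcating_tree())
        pt = (-2.5, 14.0)
        a = position_score(tree, pt)
        th = 0.7
        c, s = np.cos(th), np.sin(th)

        def rot(p):
            return (c * p[0] - s * p[1] + 3.0, s * p[0] + c * p[1] - 8.0)

        xy2 = {i: rot(p) for i, p in tree.xy.items()}
        tree2 = assign_branch_orders(DendriteTree(xy=xy2, parent=dict(tree.parent)))
        b = position_score(tree2, rot(pt))
        assert b.assigned
        assert b.score == pytest.approx(a.score, abs=1e-6)
        assert b.order == a.order


class TestOrderFractions:
    def make(self, orders):
        return [
            BranchAssignment(i, 1, o, 0.5, True, 0.0) for i, o in enumerate(orders)
        ]

    def test_degenerate_all_on_one_order(self):
        out = order_fractions(self.make([2] * 7))
        assert out == {2: 100.0, 3: 0.0, 4: 0.0, 5: 0.0}

    def test_even_split(self):
        out = order_fractions(self.make([2, 2, 3, 3]))
        assert out[2] == pytest.approx(50.0) and out[3] == pytest.approx(50.0)

    def test_sums_to_100_and_ignores_outside_interval(self):
        out = order_fractions(self.make([1, 2, 3, 4, 5, 6, 6]))
        assert sum(out.values()) == pytest.approx(100.0)
        assert set(out) == {2, 3, 4, 5}

    def test_empty_input_is_empty_percentages(self):
        assert all(v == 0.0 for v in order_fractions([]).values())


class TestSummary:
    def test_single_path_base_case(self):
        tree = path_tree(6)  # 50 um, no bifurcations
        total, bp, dens = dendrite_summary(tree)
        assert (total, bp, dens) == (pytest.approx(50.0), 0, 0.0)

    def test_spine_density_arithmetic(self):
        tree = assign_branch_orders(path_tree())
        bid = tree.branches[0].id
        total, bp, dens = dendrite_summary(tree, [(bid, 30.0, 12)])
        assert dens == pytest.approx(4.0)

    def test_unknown_segment_rejected(self):
        tree = assign_branch_orders(path_tree())
        with pytest.raises(KeyError):
            dendrite_summary(tree, [(99, 10.0, 1)])


class TestRegression:
    def test_collinear_points_r2_one(self):
        cells = [(10.0, 4.0), (20.0, 8.0), (30.0, 12.0), (40.0, 16.0)]
        res = fit_count_vs_length(cells)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(0.4)

    def test_constant_response_degenerate(self):
        res = fit_count_vs_length([(10.0, 5.0), (20.0, 5.0), (30.0, 5.0)])
        assert res["slope"] == pytest.approx(0.0)
        assert res["r"] == 0.0 and res["p"] == 1.0 and res["degenerate"] == 1.0

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_count_vs_length([(10.0, 1.0), (10.0, 2.0), (10.0, 3.0)])

    def test_spearman_option(self, rng):
        x = rng.uniform(10, 100, 30)
        y = x**2 + rng.normal(0, 5, 30)
        res = fit_count_vs_length(list(zip(x, y)), method="spearman")
        assert res["r"] > 0.95


class TestTreeJson:
    def test_round_trip(self, tmp_path):
        tree = assign_branch_orders(bifurcating_tree())
        write_tree_json(tmp_path / "t.json", tree)
        back = assign_branch_orders(read_tree_json(tmp_path / "t.json"))
        assert back.xy == tree.xy
        assert back.parent == tree.parent
        assert [b.order for b in back.branches] == [b.order for b in tree.branches]
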